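"""Expression integration and stranded nascent-transcription summaries.

Consumes an already-normalised per-gene expression table (replicate columns
are averaged; low-intensity rows indistinguishable from noise are dropped),
ranks genes for "highly expressed" selections, summarises expression per
occupancy cluster, and computes per-gene antisense read fractions downstream
of the EAG for run-on style stranded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import GeneSet
from .clustering import ClusterResult
from .coverage import ReadAlignment, _anchor_boundary

__all__ = [
    "ExpressionTable",
    "read_expression",
    "select_top_expressed",
    "cluster_expression_summary",
    "antisense_fraction",
]


@dataclass
class ExpressionTable:
    values: dict[str, float]
    replicate_count: int
    filter_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values


def read_expression(path: str, aggregate: str = "mean", low_intensity_quantile: float = 0.0) -> ExpressionTable:
    """Read a TSV (first column gene symbol, remaining columns replicate
    values), average replicates, and drop the lowest-intensity quantile.

    Gene names occurring more than once (multi-locus probes) are dropped.
    """
    if aggregate != "mean":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if not 0.0 <= low_intensity_quantile < 1.0:
        raise ValueError("low_intensity_quantile must be in [0, 1)")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene column plus at least one value column")
    gene_col = df.columns[0]
    for col in df.columns[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
    log: list[str] = []
    dup = df[gene_col].duplicated(keep=False)
    if dup.any():
        dropped = sorted(df.loc[dup, gene_col].unique())
        log.append(f"dropped {len(dropped)} multi-locus gene names: {','.join(dropped[:10])}")
        df = df[~dup]
    means = df.set_index(gene_col).astype(float).mean(axis=1)
    n_rep = df.shape[1] - 1
    if low_intensity_quantile > 0 and len(means):
        cut = float(means.quantile(low_intensity_quantile))
        n_before = len(means)
        means = means[means >= cut]
        log.append(f"low-intensity filter q={low_intensity_quantile}: {n_before} -> {len(means)} genes")
    return ExpressionTable(means.to_dict(), n_rep, log)


def select_top_expressed(et: ExpressionTable, n: int, universe: GeneSet | None = None) -> list[str]:
    """Top-n genes by expression; ties broken lexicographically by name."""
    pool = et.values
    if universe is not None:
        names = set(universe.names())
        pool = {g: v for g, v in pool.items() if g in names}
    if n > len(pool):
        raise ValueError(f"n={n} exceeds {len(pool)} available genes")
    ranked = sorted(pool.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n]]


def cluster_expression_summary(cr: ClusterResult, et: ExpressionTable) -> pd.DataFrame:
    """Per-cluster boxplot statistics of expression: n, median, quartiles and
    1.5 IQR whisker bounds.  Clusters with no expression data get NaNs."""
    rows = []
    for j in range(cr.k):
        vals = np.array([et[g] for g, c in cr.assignments.items() if c == j and g in et])
        if len(vals) == 0:
            rows.append({"cluster": j, "n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                         "whisker_lo": np.nan, "whisker_hi": np.nan})
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        rows.append({
            "cluster": j, "n": len(vals), "median": med, "q1": q1, "q3": q3,
            "whisker_lo": q1 - 1.5 * iqr, "whisker_hi": q3 + 1.5 * iqr,
        })
    return pd.DataFrame(rows)


def antisense_fraction(
    stranded_reads: list[ReadAlignment],
    gs: GeneSet,
    window: tuple[int, int] = (0, 4000),
) -> dict[str, float]:
    """Fraction of antisense reads in a window downstream of each gene's EAG.

    The window is given as (from_bp, to_bp) offsets past the EAG boundary in
    transcription orientation.  Genes with no overlapping reads get NaN.
    """
    lo_off, hi_off = window
    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in stranded_reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = {}
    for g in gs:
        a = _anchor_boundary(g, "EAG")
        if g.strand == "+":
            lo, hi = a + lo_off, a + hi_off
        else:
            lo, hi = a - hi_off, a - lo_off
        sense = anti = 0
        for r in by_chrom.get(g.chrom, ()):
            if r.start < hi and r.end > lo:
                if r.strand == g.strand:
                    sense += 1
                else:
                    anti += 1
        total = sense + anti
        out[g.name] = anti / total if total else float("nan")
    return out
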