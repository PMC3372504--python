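"""Two-condition Pol II occupancy comparison at promoter / downstream regions.

Computational analogue of a ChIP-qPCR panel: mock-normalised mean signal in
fixed offset windows relative to the TSS or the EAG, compared between an
untreated and a treated (e.g. polyadenylation-inhibited) condition as
per-gene ratios with class-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import GeneSet
from .coverage import CoverageTrack, _anchor_boundary

__all__ = ["Region", "RegionPanel", "default_region_panel", "region_signal", "condition_ratio"]

EPSILON_RPM = 0.01


@dataclass(frozen=True)
class Region:
    label: str
    anchor: str  # TSS | EAG
    from_bp: int
    to_bp: int

    def __post_init__(self):
        if self.from_bp >= self.to_bp:
            raise ValueError(f"region {self.label}: from >= to")


@dataclass
class RegionPanel:
    """Offset windows per gene class, mirroring a qPCR primer layout."""

    regions: dict[str, list[Region]]  # gene_class -> regions

    def for_class(self, gene_class: str) -> list[Region]:
        if gene_class in self.regions:
            return self.regions[gene_class]
        return self.regions.get("other", [])


def default_region_panel(min_promoter_gene_bp: int = 500) -> RegionPanel:
    """Default qPCR-style panel.

    Core-histone genes: downstream windows at +0.1-0.3 kb and +1.5-2 kb from
    the EAG; other (poly(A)+-like) genes: +0.5-1 kb, +2-3 kb and +4-5 kb;
    a TSS window at -50..+300 for all classes.  Promoter windows are skipped
    at run time for genes shorter than ``min_promoter_gene_bp`` (on very
    short genes the promoter window is not separable from the gene end).
    """
    tss = Region("TSS", "TSS", -50, 300)
    histone = [tss, Region("I", "EAG", 100, 300), Region("II", "EAG", 1500, 2000)]
    pa = [tss, Region("I", "EAG", 500, 1000), Region("II", "EAG", 2000, 3000), Region("III", "EAG", 4000, 5000)]
    return RegionPanel({"core_histone": histone, "variant_histone": pa, "other": pa})


def _region_mean(track: CoverageTrack, g, region: Region) -> float:
    a = _anchor_boundary(g, region.anchor)
    if g.strand == "+":
        lo, hi = a + region.from_bp, a + region.to_bp
    else:
        lo, hi = a - region.to_bp, a - region.from_bp
    size = track.chrom_sizes[g.chrom]
    if lo < 0 or hi > size:
        return float("nan")
    p = np.arange(lo, hi)
    s = int(track.covered[g.chrom][p // track.bin_width].sum())
    return s * track.rpm_factor / (track.bin_width * (hi - lo))


def region_signal(
    signal: CoverageTrack,
    mock: CoverageTrack,
    gs: GeneSet,
    panel: RegionPanel | None = None,
    epsilon: float = EPSILON_RPM,
    min_promoter_gene_bp: int = 500,
) -> pd.DataFrame:
    """Mock-normalised mean signal per gene and panel region.

    value = mean rpm(signal) / max(mean rpm(mock), epsilon) over the region
    in transcription orientation.  Regions extending beyond the chromosome,
    and promoter regions of genes shorter than ``min_promoter_gene_bp``,
    are reported as NaN.
    """
    if panel is None:
        panel = default_region_panel()
    rows = []
    for g in gs:
        if g.chrom not in signal.covered or g.chrom not in mock.covered:
            continue
        for region in panel.for_class(g.gene_class):
            if region.anchor == "TSS" and g.length < min_promoter_gene_bp:
                val = float("nan")
            else:
                s = _region_mean(signal, g, region)
                m = _region_mean(mock, g, region)
                val = s / max(m, epsilon) if np.isfinite(s) and np.isfinite(m) else float("nan")
            rows.append({"gene": g.name, "gene_class": g.gene_class, "region": region.label, "value": val})
    return pd.DataFrame(rows)


def condition_ratio(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene treated/untreated ratios and class-level bootstrap summaries.

    Returns (per_gene, summary).  Undefined region values propagate as NaN
    and are excluded from the summaries; the count of exclusions is reported.
    """
    key = ["gene", "gene_class", "region"]
    merged = treated.merge(untreated, on=key, suffixes=("_treated", "_untreated"), validate="one_to_one")
    if len(merged) != len(treated) or len(merged) != len(untreated):
        raise ValueError("treated and untreated gene/region sets are not congruent")
    merged["ratio"] = merged["value_treated"] / merged["value_untreated"]
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2
    rows = []
    for (cls, region), grp in merged.groupby(["gene_class", "region"], sort=True):
        ratios = grp["ratio"].to_numpy()
        ok = np.isfinite(ratios)
        vals = ratios[ok]
        n_excl = int((~ok).sum())
        if len(vals) == 0:
            rows.append({"gene_class": cls, "region": region, "n": 0, "n_undefined": n_excl,
                         "mean_ratio": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
        rows.append({
            "gene_class": cls, "region": region, "n": len(vals), "n_undefined": n_excl,
            "mean_ratio": float(vals.mean()),
            "ci_lo": float(np.quantile(boots, alpha)),
            "ci_hi": float(np.quantile(boots, 1 - alpha)),
        })
    return merged, pd.DataFrame(rows)
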