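"""End-to-end analyses: annotation filtering -> coverage -> clustering ->
pause metrics -> expression stratification, and the two-condition
perturbation comparison.  A plain-YAML config is the single source of truth;
every run writes a manifest with per-stage gene counts so the filter
waterfall (universe -> isolated -> clustered) is auditable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import annotations as ann
from . import clustering as clu
from . import coverage as cov
from . import pause_metrics as pm
from . import perturbation as pert
from . import stratify as strat

__all__ = ["AnalysisConfig", "run_eag_analysis", "run_perturbation_analysis"]


@dataclass
class AnalysisConfig:
    signal_reads: str = ""
    mock_reads: str = ""
    nascent_reads: str | None = None
    annotation: str = ""
    annotation_format: str = "bed12"
    chrom_sizes: str = ""
    expression: str | None = None
    gene_class_table: str | None = None
    treated_signal_reads: str | None = None
    treated_mock_reads: str | None = None
    flank_bp: int = 4000
    bin_width: int = 50
    extension_bp: int = 200
    read_length: int = 32
    k: int = 2
    restarts: int = 50
    seed: int = 0
    min_distance_bp: int = 4000
    collapse_rule: str = "longest"
    low_intensity_quantile: float = 0.0
    smoothing_bins: int = 3
    narrow_max_extent_bp: int = 1000
    outdir: str = "polpause_out"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh, sort_keys=True)

    def validate(self, require_tracks: bool = True) -> None:
        if require_tracks:
            for label in ("signal_reads", "mock_reads", "annotation", "chrom_sizes"):
                p = getattr(self, label)
                if not p:
                    raise ValueError(f"config field {label!r} is required")
                if not os.path.exists(p):
                    raise ValueError(f"config field {label!r}: file not found: {p}")
        for label in ("nascent_reads", "expression", "gene_class_table", "treated_signal_reads", "treated_mock_reads"):
            p = getattr(self, label)
            if p and not os.path.exists(p):
                raise ValueError(f"config field {label!r}: file not found: {p}")
        if self.annotation_format not in ("bed12", "refflat", "gtf"):
            raise ValueError(f"config field 'annotation_format': unknown format {self.annotation_format!r}")
        for label, lo in (("flank_bp", 1), ("bin_width", 1), ("extension_bp", 1), ("k", 1),
                          ("restarts", 1), ("min_distance_bp", 0), ("smoothing_bins", 1),
                          ("narrow_max_extent_bp", 1)):
            v = getattr(self, label)
            if not isinstance(v, int) or v < lo:
                raise ValueError(f"config field {label!r}: must be an integer >= {lo}, got {v!r}")
        if self.flank_bp % self.bin_width:
            raise ValueError("config field 'flank_bp': must be a multiple of bin_width")
        if not 0.0 <= self.low_intensity_quantile < 1.0:
            raise ValueError("config field 'low_intensity_quantile': must be in [0, 1)")
        if self.collapse_rule not in ("longest", "union"):
            raise ValueError(f"config field 'collapse_rule': unknown rule {self.collapse_rule!r}")


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_class_table(path: str) -> tuple[list[str], list[str]]:
    core, variant = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gi, ci = header.index("gene"), header.index("class")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[ci] == "core_histone":
                core.append(f[gi])
            elif f[ci] == "variant_histone":
                variant.append(f[gi])
    return core, variant


def _load_track(
    reads_path: str, cfg: AnalysisConfig, sizes: dict[str, int], normalization: str = "rpm"
) -> cov.CoverageTrack:
    reads = cov.read_bed6(reads_path)
    frags = cov.extend_reads(reads, cfg.extension_bp, sizes)
    return cov.build_coverage(frags, cfg.bin_width, sizes, normalization=normalization)


@dataclass
class StageLog:
    manifest: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.manifest.setdefault("stages", []).append({"stage": stage, **info})


def run_eag_analysis(cfg: AnalysisConfig, truth_labels: dict[str, str] | None = None) -> dict:
    """Full EAG-anchored analysis; returns the manifest dict and writes all
    artifact tables into ``cfg.outdir``."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    log = StageLog()
    log.manifest["seed"] = cfg.seed
    log.manifest["inputs"] = {
        p: _md5(getattr(cfg, p))
        for p in ("signal_reads", "mock_reads", "annotation", "chrom_sizes")
    }
    out = lambda name: os.path.join(cfg.outdir, name)

    try:
        sizes = cov.read_chrom_sizes(cfg.chrom_sizes)
        gs = ann.read_gene_models(cfg.annotation, cfg.annotation_format)
        n_tx = len(gs)
        gs = ann.collapse_transcripts(gs, cfg.collapse_rule)
        n_genes = len(gs)
        kept = ann.filter_isolated(gs, cfg.min_distance_bp)
        if cfg.gene_class_table:
            core, variant = _read_class_table(cfg.gene_class_table)
            kept = ann.assign_gene_class(kept, core, variant)
        ann.write_bed6(kept, out("genes_kept.bed"))
        ann.write_filter_log(gs, kept, out("filter_log.tsv"))
        log.record("annotations", transcripts=n_tx, genes=n_genes, isolated=len(kept))
    except Exception as e:
        raise RuntimeError(f"stage 'annotations' failed: {e}") from e

    try:
        signal = _load_track(cfg.signal_reads, cfg, sizes)
        mock = _load_track(cfg.mock_reads, cfg, sizes)
        sig_mat = cov.anchor_matrix(signal, kept, "EAG", cfg.flank_bp)
        mock_mat = cov.anchor_matrix(mock, kept, "EAG", cfg.flank_bp)
        sig_mat.to_tsv(out("signal_eag_matrix.tsv"))
        mock_mat.to_tsv(out("mock_eag_matrix.tsv"))
        with open(out("matrix_meta.json"), "w") as fh:
            json.dump({"anchor": "EAG", "flank_bp": cfg.flank_bp, "bin_width": cfg.bin_width,
                       "signal_fragments": signal.total_fragments,
                       "mock_fragments": mock.total_fragments}, fh, indent=1)
        log.record("coverage", signal_fragments=signal.total_fragments,
                   mock_fragments=mock.total_fragments, matrix_genes=sig_mat.n_genes)
    except Exception as e:
        raise RuntimeError(f"stage 'coverage' failed: {e}") from e

    try:
        cr = clu.kmeans_cluster(sig_mat, cfg.k, cfg.seed, cfg.restarts)
        cr.to_tsv(out("cluster_assignments.tsv"))
        profiles, csizes = clu.cluster_profiles(sig_mat, cr)
        with open(out("cluster_profiles.tsv"), "w") as fh:
            fh.write("cluster\tn\t" + "\t".join(f"{o:+.0f}" for o in sig_mat.offsets) + "\n")
            for j in range(cr.k):
                fh.write(f"{j}\t{csizes[j]}\t" + "\t".join(f"{v:.6g}" for v in profiles[j]) + "\n")
        info = {"k": cfg.k, "sizes": {str(j): csizes[j] for j in sorted(csizes)}, "inertia": cr.inertia}
        if truth_labels:
            order = [g for g in sig_mat.genes if g in truth_labels]
            ari = clu.adjusted_rand_index([truth_labels[g] for g in order], [cr.assignments[g] for g in order])
            info["ari_vs_truth"] = round(ari, 6)
        log.record("clustering", **info)
    except Exception as e:
        raise RuntimeError(f"stage 'clustering' failed: {e}") from e

    try:
        metrics = pm.compute_pause_metrics(sig_mat, mock_mat, signal, kept,
                                           cfg.smoothing_bins, cfg.narrow_max_extent_bp)
        pm.write_metrics_tsv(metrics, out("pause_metrics.tsv"))
        n_shapes = {}
        for v in metrics.values():
            n_shapes[v.shape_class] = n_shapes.get(v.shape_class, 0) + 1
        log.record("pause_metrics", genes=len(metrics), shapes=n_shapes)
    except Exception as e:
        raise RuntimeError(f"stage 'pause_metrics' failed: {e}") from e

    try:
        info = {}
        if cfg.expression:
            et = strat.read_expression(cfg.expression, "mean", cfg.low_intensity_quantile)
            summary = strat.cluster_expression_summary(cr, et)
            summary.to_csv(out("cluster_expression.tsv"), sep="\t", index=False)
            n_top = min(100, len([g for g in kept.names() if g in et]))
            top = strat.select_top_expressed(et, n_top, kept)
            with open(out("top_expressed.txt"), "w") as fh:
                fh.write("\n".join(top) + "\n")
            info["expression_genes"] = len(et)
        if cfg.nascent_reads:
            nascent = cov.read_bed6(cfg.nascent_reads)
            af = strat.antisense_fraction(nascent, kept, (0, cfg.flank_bp))
            with open(out("antisense_fraction.tsv"), "w") as fh:
                fh.write("gene\tantisense_fraction\n")
                for g, f in af.items():
                    fh.write(f"{g}\t{f:.6g}\n")
            import numpy as np

            defined = [f for f in af.values() if np.isfinite(f)]
            info["mean_antisense_fraction"] = float(np.mean(defined)) if defined else None
        log.record("stratify", **info)
    except Exception as e:
        raise RuntimeError(f"stage 'stratify' failed: {e}") from e

    log.manifest["complete"] = True
    with open(out("manifest.json"), "w") as fh:
        json.dump(log.manifest, fh, indent=1, sort_keys=True)
    return log.manifest


def run_perturbation_analysis(cfg: AnalysisConfig) -> dict:
    """Untreated-vs-treated region comparison; needs the treated tracks."""
    cfg.validate()
    if not cfg.treated_signal_reads or not cfg.treated_mock_reads:
        raise ValueError("perturbation analysis requires treated_signal_reads and treated_mock_reads")
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)
    sizes = cov.read_chrom_sizes(cfg.chrom_sizes)
    gs = ann.collapse_transcripts(ann.read_gene_models(cfg.annotation, cfg.annotation_format), cfg.collapse_rule)
    gs = ann.filter_isolated(gs, cfg.min_distance_bp)
    if cfg.gene_class_table:
        core, variant = _read_class_table(cfg.gene_class_table)
        gs = ann.assign_gene_class(gs, core, variant)
    panel = pert.default_region_panel()
    # raw (absolute) coverage: condition ratios compare per-locus read rates,
    # as a qPCR %input measurement would; per-million scaling would fold the
    # perturbation's global occupancy change into every locus
    untreated = pert.region_signal(_load_track(cfg.signal_reads, cfg, sizes, "raw"),
                                   _load_track(cfg.mock_reads, cfg, sizes, "raw"), gs, panel)
    treated = pert.region_signal(_load_track(cfg.treated_signal_reads, cfg, sizes, "raw"),
                                 _load_track(cfg.treated_mock_reads, cfg, sizes, "raw"), gs, panel)
    per_gene, summary = pert.condition_ratio(treated, untreated, seed=cfg.seed)
    per_gene.to_csv(out("region_ratios.tsv"), sep="\t", index=False)
    summary.to_csv(out("region_ratio_summary.tsv"), sep="\t", index=False)
    manifest = {"seed": cfg.seed, "genes": len(gs), "regions": int(len(per_gene)), "complete": True}
    with open(out("perturbation_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
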