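"""Parametric simulator of Pol II occupancy with planted 3' pause shapes.

A synthetic chromosome carries well-separated genes of two classes whose
per-base Pol II intensity is

    intensity(x) = background
                 + tss_amplitude * Gaussian(x; tss + offset, sd)
                 + body_level    * 1[x in gene body]
                 + pause_amplitude * exp(-d / lambda) * 1[0 < d <= cap]

with d the transcription-orientation distance past the end of the annotated
gene.  Histone-type genes decay sharply (lambda = 250 bp, capped at 1 kb);
poly(A)+-type genes decay slowly (lambda = 1500 bp, capped at 8 kb).  Short
32-bp tags are Poisson-sampled from the normalised intensity, so the whole
read-extension / binning / clustering / metric pipeline can be exercised
against known truth.  Mock tracks use the same sampler with all gene
amplitudes zero; nascent (run-on style) tracks keep strand of origin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .annotations import GeneModel, GeneSet
from .coverage import ReadAlignment, write_bed6_reads, write_chrom_sizes

__all__ = [
    "OccupancyParams",
    "SyntheticTruth",
    "make_genome",
    "occupancy_intensity",
    "genome_intensity",
    "sample_reads",
    "apply_condition",
    "simulate_scenario",
    "ScenarioData",
]

CHROM = "chrS"


@dataclass(frozen=True)
class OccupancyParams:
    """Per-gene occupancy model parameters (intensity in arbitrary units/bp)."""

    tss_amplitude: float = 8.0
    tss_offset_bp: int = 30  # promoter-proximal stall sits 20-50 nt past the TSS
    tss_sd_bp: float = 150.0
    body_level: float = 1.0
    pause_amplitude: float = 6.0
    pause_decay_bp: float = 1500.0
    pause_cap_bp: int = 8000
    background_rate: float = 0.05
    gene_class: str = "other"

    def __post_init__(self):
        if min(self.tss_amplitude, self.body_level, self.pause_amplitude, self.background_rate) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.pause_decay_bp <= 0:
            raise ValueError("pause_decay_bp must be > 0")


HISTONE_PARAMS = OccupancyParams(pause_decay_bp=250.0, pause_cap_bp=1000, gene_class="core_histone")
PA_PARAMS = OccupancyParams(pause_decay_bp=1500.0, pause_cap_bp=8000, gene_class="other")
MOCK_PARAMS = OccupancyParams(tss_amplitude=0.0, body_level=0.0, pause_amplitude=0.0, gene_class="other")


@dataclass
class SyntheticTruth:
    """Planted ground truth written before any reads are sampled."""

    params: dict[str, OccupancyParams]  # gene -> params
    classes: dict[str, str]  # gene -> class label
    expected_extent_bp: dict[str, float]
    seed: int = 0
    depth: float = 0.0
    read_length: int = 32
    condition: str = "baseline"

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tclass\tpause_decay_bp\tpause_cap_bp\tpause_amplitude\texpected_extent_bp\tcondition\n")
            for g, p in self.params.items():
                fh.write(
                    f"{g}\t{self.classes[g]}\t{p.pause_decay_bp:.0f}\t{p.pause_cap_bp}\t"
                    f"{p.pause_amplitude:.3g}\t{self.expected_extent_bp[g]:.0f}\t{self.condition}\n"
                )


def _expected_extent(p: OccupancyParams) -> float:
    """Distance where the noiseless pause component falls to the background
    level, capped at the planted cap."""
    if p.pause_amplitude <= p.background_rate or p.background_rate == 0:
        return 0.0 if p.pause_amplitude == 0 else float(p.pause_cap_bp)
    return float(min(p.pause_cap_bp, p.pause_decay_bp * np.log(p.pause_amplitude / p.background_rate)))


def make_genome(
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (1000, 6000),
    spacing_range: tuple[int, int] = (20000, 30000),
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, int], GeneSet, SyntheticTruth]:
    """Lay out non-overlapping genes with random strands along one chromosome.

    ``class_mix`` maps class label -> proportion (default half core-histone,
    half poly(A)+-like).  Spacing >= 20 kb (the default) guarantees every
    gene passes a 4-kb isolation filter; a spacing range of 0.8-1 kb mimics
    a clustered histone locus where none do.
    """
    if class_mix is None:
        class_mix = {"core_histone": 0.5, "other": 0.5}
    if gene_length_range[0] <= 0 or spacing_range[0] < 0:
        raise ValueError("ranges must be positive")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = sorted(class_mix)
    # deterministic class counts (largest remainder), then shuffled placement
    counts = {c: int(class_mix[c] * n_genes) for c in labels}
    rest = n_genes - sum(counts.values())
    for c in labels[:rest]:
        counts[c] += 1
    class_seq = [c for c in labels for _ in range(counts[c])]
    rng.shuffle(class_seq)

    genes, params, classes, extents = [], {}, {}, {}
    pos = int(rng.integers(spacing_range[0], spacing_range[1] + 1))
    for i, cls in enumerate(class_seq):
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"g{i:04d}"
        start, end = pos, pos + length
        if cls == "core_histone":
            ex_s, ex_e = (start,), (end,)
            p = HISTONE_PARAMS
        else:
            n_ex = int(rng.integers(1, 6))
            cuts = sorted(rng.choice(np.arange(1, length), size=2 * (n_ex - 1), replace=False)) if n_ex > 1 else []
            bounds = [start] + [start + c for c in cuts] + [end]
            ex_s = tuple(bounds[i] for i in range(0, len(bounds) - 1, 2))
            ex_e = tuple(bounds[i] for i in range(1, len(bounds), 2))
            p = PA_PARAMS
        genes.append(GeneModel(CHROM, start, end, strand, name, name, ex_s, ex_e, cls if cls in
                               ("core_histone", "variant_histone") else "other"))
        params[name] = p
        classes[name] = cls
        extents[name] = _expected_extent(p)
        pos = end + int(rng.integers(spacing_range[0], spacing_range[1] + 1))
    chrom_sizes = {CHROM: pos}
    gs = GeneSet(genes, [f"synthetic genome: {n_genes} genes, seed={seed}"])
    truth = SyntheticTruth(params, classes, extents, seed=seed)
    return chrom_sizes, gs, truth


def occupancy_intensity(gene: GeneModel, p: OccupancyParams, flank: int = 8000) -> np.ndarray:
    """Per-base intensity over ``gene +/- flank`` in genomic coordinates."""
    if flank < p.pause_cap_bp:
        raise ValueError("flank must cover the pause cap")
    lo = gene.start - flank
    x = np.arange(lo, gene.end + flank)
    out = np.full(len(x), p.background_rate, dtype=float)
    if gene.strand == "+":
        tss_mu = gene.start + p.tss_offset_bp
        d = x - gene.end + 1  # distance past the EAG boundary
    else:
        tss_mu = gene.end - 1 - p.tss_offset_bp
        d = gene.start - x
    out += p.tss_amplitude * np.exp(-0.5 * ((x - tss_mu) / p.tss_sd_bp) ** 2)
    out += p.body_level * ((x >= gene.start) & (x < gene.end))
    pause = (d > 0) & (d <= p.pause_cap_bp)
    out[pause] += p.pause_amplitude * np.exp(-d[pause] / p.pause_decay_bp)
    return out


def genome_intensity(
    chrom_sizes: dict[str, int],
    gs: GeneSet,
    params: dict[str, OccupancyParams],
    background_rate: float | None = None,
    flank: int = 8000,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Genome-wide per-base intensity and per-base strand-of-origin.

    Returns (intensity, owner) keyed by chromosome; owner is +1 where the
    local signal comes from a plus-strand gene, -1 for minus, 0 for
    background-only bases (assignment by the dominant gene component).
    """
    bg = background_rate
    if bg is None:
        bg = max((p.background_rate for p in params.values()), default=0.05)
    intensity = {c: np.full(n, bg, dtype=float) for c, n in chrom_sizes.items()}
    owner = {c: np.zeros(n, dtype=np.int8) for c, n in chrom_sizes.items()}
    for g in gs:
        p = params[g.name]
        contrib = occupancy_intensity(g, dataclasses.replace(p, background_rate=0.0), flank)
        lo = g.start - flank
        hi = g.end + flank
        s = max(0, lo)
        e = min(chrom_sizes[g.chrom], hi)
        seg = contrib[s - lo : e - lo]
        intensity[g.chrom][s:e] += seg
        sgn = 1 if g.strand == "+" else -1
        owner[g.chrom][s:e] = np.where(seg > bg, sgn, owner[g.chrom][s:e])
    return intensity, owner


def sample_reads(
    intensity: dict[str, np.ndarray],
    depth: float,
    read_len: int = 32,
    mode: str = "chip",
    seed: int = 0,
    owner: dict[str, np.ndarray] | None = None,
) -> list[ReadAlignment]:
    """Poisson-sample 32-bp tags whose 5' starts follow the intensity.

    Per-base counts are Poisson(depth * intensity / total intensity), so the
    dataset size is Poisson(depth).  chip/mock reads get a random strand;
    nascent reads inherit the strand of the gene that generated them
    (``owner``), with background bases getting a random strand.
    """
    if mode not in ("chip", "mock", "nascent"):
        raise ValueError(f"unknown mode {mode!r}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    total = sum(float(v.sum()) for v in intensity.values())
    if total <= 0:
        raise ValueError("zero-mass intensity")
    if mode == "nascent" and owner is None:
        raise ValueError("nascent mode requires a strand-of-origin map")
    rng = np.random.default_rng(seed)
    reads = []
    for chrom in sorted(intensity):
        lam = depth * intensity[chrom] / total
        counts = rng.poisson(lam)
        starts5 = np.repeat(np.arange(len(lam)), counts)
        if mode == "nascent":
            own = owner[chrom][starts5]
            rand = rng.random(len(starts5)) < 0.5
            plus = np.where(own != 0, own > 0, rand)
        else:
            plus = rng.random(len(starts5)) < 0.5
        size = len(lam)
        for p5, is_plus in zip(starts5, plus):
            if is_plus:
                s, e = p5, min(int(p5) + read_len, size)
            else:
                s, e = max(int(p5) - read_len + 1, 0), int(p5) + 1
            reads.append(ReadAlignment(chrom, int(s), int(e), "+" if is_plus else "-"))
    return reads


def apply_condition(truth: SyntheticTruth, gamma_downstream: float = 2.0, delta_tss: float = 0.5) -> SyntheticTruth:
    """Polyadenylation-inhibition-style perturbation.

    Scales pause amplitude by gamma and TSS amplitude by delta on poly(A)+
    -class genes; core-histone genes are untouched.
    """
    if gamma_downstream <= 0 or delta_tss <= 0:
        raise ValueError("condition factors must be > 0")
    new_params = {}
    for g, p in truth.params.items():
        if truth.classes[g] == "core_histone":
            new_params[g] = p
        else:
            new_params[g] = dataclasses.replace(
                p,
                pause_amplitude=p.pause_amplitude * gamma_downstream,
                tss_amplitude=p.tss_amplitude * delta_tss,
            )
    return SyntheticTruth(
        new_params,
        dict(truth.classes),
        {g: _expected_extent(p) for g, p in new_params.items()},
        seed=truth.seed,
        depth=truth.depth,
        read_length=truth.read_length,
        condition=f"polyA-inhibited(gamma={gamma_downstream},delta={delta_tss})",
    )


@dataclass
class ScenarioData:
    """In-memory bundle of one simulated experiment."""

    chrom_sizes: dict[str, int]
    genes: GeneSet
    truth: SyntheticTruth
    reads: dict[str, list[ReadAlignment]]  # track name -> reads
    expression: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def simulate_scenario(
    n_genes: int = 200,
    reads_per_gene: float = 200.0,
    mock_reads_per_gene: float = 100.0,
    nascent_reads_per_gene: float = 100.0,
    class_mix: dict[str, float] | None = None,
    gene_length_range: tuple[int, int] = (1000, 6000),
    spacing_range: tuple[int, int] = (20000, 30000),
    read_len: int = 32,
    seed: int = 0,
    condition: tuple[float, float] | None = None,
    nascent_background: bool = False,
) -> ScenarioData:
    """Generate a full experiment: genome, gene models, truth, and reads for
    Pol II ChIP, mock and (optionally strand-pure) nascent tracks.

    ``condition=(gamma, delta)`` applies the polyadenylation-inhibition
    perturbation before sampling.  With ``nascent_background=False`` the
    nascent track has zero background so every nascent read is gene-derived
    (and hence sense-stranded).
    """
    chrom_sizes, gs, truth = make_genome(n_genes, gene_length_range, spacing_range, class_mix, seed)
    truth.depth = reads_per_gene * n_genes
    truth.read_length = read_len
    depth_scale = 1.0
    if condition is not None:
        base_int, _ = genome_intensity(chrom_sizes, gs, truth.params)
        truth = apply_condition(truth, *condition)
        cond_int, _ = genome_intensity(chrom_sizes, gs, truth.params)
        # absolute (input-calibrated) sampling: the per-intensity read rate is
        # held constant across conditions, so a perturbation that adds occupancy
        # yields proportionally more reads rather than redistributing a fixed total
        depth_scale = sum(float(v.sum()) for v in cond_int.values()) / sum(
            float(v.sum()) for v in base_int.values()
        )
    intensity, owner = genome_intensity(chrom_sizes, gs, truth.params)
    mock_int = {c: np.full(n, MOCK_PARAMS.background_rate) for c, n in chrom_sizes.items()}
    nas_params = truth.params
    nas_bg = None if nascent_background else 0.0
    nas_int, nas_owner = genome_intensity(chrom_sizes, gs, nas_params, background_rate=nas_bg)
    ss = np.random.SeedSequence(seed)
    s_sig, s_mock, s_nas, s_expr = [int(x) for x in ss.generate_state(4) >> np.uint32(1)]
    reads = {
        "polii": sample_reads(intensity, reads_per_gene * n_genes * depth_scale, read_len, "chip", s_sig),
        "mock": sample_reads(mock_int, mock_reads_per_gene * n_genes, read_len, "mock", s_mock),
        "nascent": sample_reads(nas_int, nascent_reads_per_gene * n_genes, read_len, "nascent", s_nas, nas_owner),
    }
    # expression proportional to body level with mild replicate noise
    rng = np.random.default_rng(s_expr)
    expression = {
        g.name: truth.params[g.name].body_level * (8.0 if truth.classes[g.name] == "core_histone" else 4.0)
        * float(np.exp(rng.normal(0, 0.1)))
        for g in gs
    }
    config = {
        "n_genes": n_genes,
        "reads_per_gene": reads_per_gene,
        "mock_reads_per_gene": mock_reads_per_gene,
        "nascent_reads_per_gene": nascent_reads_per_gene,
        "gene_length_range": list(gene_length_range),
        "spacing_range": list(spacing_range),
        "read_len": read_len,
        "seed": seed,
        "condition": list(condition) if condition else None,
        "nascent_background": nascent_background,
    }
    return ScenarioData(chrom_sizes, gs, truth, reads, expression, config)


def write_scenario(sc: ScenarioData, outdir: str) -> None:
    """Write chrom.sizes, BED12 genes, BED6 reads per track, truth TSV,
    expression TSV and the scenario config."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_chrom_sizes(sc.chrom_sizes, os.path.join(outdir, "chrom.sizes"))
    with open(os.path.join(outdir, "genes.bed12"), "w") as fh:
        for g in sc.genes:
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offs = ",".join(str(s - g.start) for s in g.exon_starts)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t{g.start}\t{g.end}\t0\t"
                f"{len(g.exon_starts)}\t{sizes}\t{offs}\n"
            )
    for track, reads in sc.reads.items():
        write_bed6_reads(reads, os.path.join(outdir, f"{track}.bed"))
    sc.truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    with open(os.path.join(outdir, "expression.tsv"), "w") as fh:
        fh.write("gene\trep1\trep2\trep3\trep4\trep5\n")
        rng = np.random.default_rng(sc.truth.seed + 7)
        for g, v in sc.expression.items():
            reps = v * np.exp(rng.normal(0, 0.05, size=5))
            fh.write(g + "\t" + "\t".join(f"{r:.4f}" for r in reps) + "\n")
    with open(os.path.join(outdir, "scenario.yaml"), "w") as fh:
        yaml.safe_dump(sc.config, fh, sort_keys=True)
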