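"""Read extension, binned coverage and orientation-normalised anchored matrices.

ChIP-seq tags mark only the 5' end of immunoprecipitated fragments, so each
read is extended in its own orientation to the expected fragment length
(200 bp by default) before coverage is computed.  Coverage is kept as
*covered base-pairs per bin* in exact integer arithmetic; the user-facing
bin value is the mean per-base fragment depth (covered bp / bin width),
optionally scaled to reads per million (rpm).

Anchored matrices place each gene in transcription orientation: column
indices always increase downstream, so minus-strand rows are reversed.
Windows are anchored at the strand-aware *boundary* coordinate of the
anchor (for a plus-strand gene the EAG boundary is its BED ``end``; for a
minus-strand gene it is its ``start``), which makes the construction exactly
symmetric under a genome mirror plus strand flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import GeneModel, GeneSet

__all__ = [
    "ReadAlignment",
    "Fragment",
    "CoverageTrack",
    "AnchorMatrix",
    "read_bed6",
    "write_bed6_reads",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "extend_reads",
    "build_coverage",
    "anchor_matrix",
    "scaled_gene_matrix",
    "mean_profile",
    "write_bedgraph",
]

DEFAULT_READ_LENGTH = 32
DEFAULT_EXTENSION = 200
DEFAULT_BIN_WIDTH = 50


@dataclass(frozen=True)
class ReadAlignment:
    """A uniquely mapped sequencing tag (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    """A directionally extended read standing in for the sequenced fragment."""

    chrom: str
    start: int
    end: int
    strand: str
    source_read_id: int = -1

    @property
    def length(self) -> int:
        return self.end - self.start


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed6(path: str) -> list[ReadAlignment]:
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 fields, got {len(f)}")
            if f[5] not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {f[5]!r}")
            reads.append(ReadAlignment(f[0], int(f[1]), int(f[2]), f[5]))
    return reads


def write_bed6_reads(reads, path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


def read_bam(path: str) -> list[ReadAlignment]:
    """Mapped primary alignments from a BAM file (requires pysam)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(ReadAlignment(aln.reference_name, aln.reference_start, aln.reference_end, strand))
    return reads


def extend_reads(
    reads,
    extension_length: int = DEFAULT_EXTENSION,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Fragment]:
    """Extend each read from its 5' end to ``extension_length`` bp in read
    orientation, clipping at chromosome edges.

    A read already longer than the extension keeps its native length.
    """
    frags = []
    for i, r in enumerate(reads):
        if chrom_sizes is not None:
            if r.chrom not in chrom_sizes:
                raise ValueError(f"read {i}: chromosome {r.chrom} not in chrom sizes")
            size = chrom_sizes[r.chrom]
            if r.start < 0 or r.end > size:
                raise ValueError(f"read {i}: [{r.start},{r.end}) outside {r.chrom} (size {size})")
        else:
            size = None
        e = max(extension_length, r.length)
        if r.strand == "+":
            s, t = r.start, r.start + e
        else:
            s, t = r.end - e, r.end
        if s < 0:
            s = 0
        if size is not None and t > size:
            t = size
        frags.append(Fragment(r.chrom, s, t, r.strand, i))
    return frags


class CoverageTrack:
    """Binned, strand-filtered genome coverage.

    Internally stores covered base-pairs per bin as int64 (exact); the
    value of a bin is covered bp / bin width, times 1e6/total fragments
    when rpm-normalised.
    """

    def __init__(
        self,
        bin_width: int,
        chrom_sizes: dict[str, int],
        covered: dict[str, np.ndarray],
        total_fragments: int,
        strand_mode: str = "both",
        normalization: str = "raw",
    ):
        self.bin_width = bin_width
        self.chrom_sizes = dict(chrom_sizes)
        self.covered = covered  # int64 covered-bp per bin
        self.total_fragments = total_fragments
        self.strand_mode = strand_mode
        self.normalization = normalization

    @property
    def rpm_factor(self) -> float:
        """1e6 / total fragments under rpm normalisation, else 1."""
        return 1e6 / self.total_fragments if self.normalization == "rpm" else 1.0

    @property
    def scale(self) -> float:
        """Multiplier from covered-bp-per-bin to the reported bin value."""
        return self.rpm_factor / self.bin_width

    def values(self, chrom: str) -> np.ndarray:
        # divide last so raw values match per-base arithmetic bit-for-bit
        return self.covered[chrom] * self.rpm_factor / self.bin_width

    def total_covered_bp(self) -> int:
        return int(sum(int(a.sum()) for a in self.covered.values()))

    def n_bins(self, chrom: str) -> int:
        return len(self.covered[chrom])


def build_coverage(
    frags,
    bin_width: int = DEFAULT_BIN_WIDTH,
    chrom_sizes: dict[str, int] | None = None,
    strand_mode: str = "both",
    normalization: str = "raw",
) -> CoverageTrack:
    """Bin fragment coverage genome-wide.

    Each bin records the total base-pairs of selected-strand fragments it
    contains; bin value = covered bp / bin width (mean per-base depth).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if strand_mode not in ("both", "plus", "minus"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if normalization not in ("raw", "rpm"):
        raise ValueError(f"unknown normalization {normalization!r}")
    want = {"both": "+-", "plus": "+", "minus": "-"}[strand_mode]
    frags = [f for f in frags if f.strand in want]
    if normalization == "rpm" and not frags:
        raise ValueError("rpm normalization requires at least one fragment")
    if chrom_sizes is None:
        chrom_sizes = {}
        for f in frags:
            chrom_sizes[f.chrom] = max(chrom_sizes.get(f.chrom, 0), f.end)
    covered: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[Fragment]] = {c: [] for c in chrom_sizes}
    for f in frags:
        if f.chrom not in by_chrom:
            raise ValueError(f"fragment on {f.chrom} not in chrom sizes")
        by_chrom[f.chrom].append(f)
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_width)
        diff = np.zeros(size + 1, dtype=np.int64)
        for f in by_chrom[chrom]:
            s, e = max(0, f.start), min(size, f.end)
            if s < e:
                diff[s] += 1
                diff[e] -= 1
        depth = np.cumsum(diff[:-1])
        padded = np.zeros(n_bins * bin_width, dtype=np.int64)
        padded[:size] = depth
        covered[chrom] = padded.reshape(n_bins, bin_width).sum(axis=1)
    return CoverageTrack(bin_width, chrom_sizes, covered, len(frags), strand_mode, normalization)


@dataclass
class AnchorMatrix:
    """Genes x bins occupancy matrix in transcription orientation.

    ``values[i, j]`` is the mean per-base density of gene i in the j-th
    window downstream-increasing bin.  ``offsets`` are bin-midpoint offsets
    from the anchor boundary in bp (negative = upstream).
    """

    genes: list[str]
    anchor: str  # TSS | EAG | scaled_body
    flank_bp: int
    bin_width: int
    values: np.ndarray
    n_body_bins: int = 0
    clipped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    dropped: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """Bin midpoint offsets from the anchor (flank bins only layout)."""
        if self.anchor == "scaled_body":
            raise ValueError("scaled_body matrices have no uniform offset axis")
        return -self.flank_bp + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def eag_column(self) -> int:
        """First column at/after the anchor boundary (first downstream bin)."""
        return self.flank_bp // self.bin_width

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def subset(self, names) -> "AnchorMatrix":
        idx = [self.genes.index(n) for n in names]
        return AnchorMatrix(
            [self.genes[i] for i in idx],
            self.anchor,
            self.flank_bp,
            self.bin_width,
            self.values[idx],
            self.n_body_bins,
            self.clipped[idx] if len(self.clipped) else self.clipped,
            list(self.dropped),
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            if self.anchor == "scaled_body":
                header = [f"bin{j}" for j in range(self.n_bins)]
            else:
                header = [f"{o:+.0f}" for o in self.offsets]
            fh.write("gene\t" + "\t".join(header) + "\n")
            for g, row in zip(self.genes, self.values):
                fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _anchor_boundary(g: GeneModel, anchor: str) -> int:
    """Strand-aware boundary coordinate of an anchor (0-based, between-bases)."""
    if anchor == "TSS":
        return g.start if g.strand == "+" else g.end
    if anchor == "EAG":
        return g.end if g.strand == "+" else g.start
    raise ValueError(f"unknown anchor {anchor!r}")


def _window_sums(track: CoverageTrack, chrom: str, pos: np.ndarray, n_cols: int, width: int) -> np.ndarray:
    """Integer covered-bp sums of ``n_cols`` consecutive ``width``-base
    windows at per-base positions ``pos`` (out-of-range bases count 0)."""
    size = track.chrom_sizes[chrom]
    cov = track.covered[chrom]
    vals = np.zeros(len(pos), dtype=np.int64)
    ok = (pos >= 0) & (pos < size)
    vals[ok] = cov[pos[ok] // track.bin_width]
    return vals.reshape(n_cols, width).sum(axis=1), bool((~ok).any())


def anchor_matrix(track: CoverageTrack, gs: GeneSet, anchor: str = "EAG", flank_bp: int = 4000) -> AnchorMatrix:
    """Per-gene density in ``[anchor - flank, anchor + flank)``, oriented so
    columns increase in the direction of transcription."""
    w = track.bin_width
    if flank_bp % w:
        raise ValueError(f"flank_bp {flank_bp} not a multiple of bin_width {w}")
    n_cols = 2 * flank_bp // w
    names, rows, clipped, dropped = [], [], [], []
    for g in gs:
        if g.chrom not in track.covered:
            dropped.append(g.name)
            continue
        a = _anchor_boundary(g, anchor)
        pos = np.arange(a - flank_bp, a + flank_bp)
        if g.strand == "-":
            pos = pos[::-1]
        sums, clip = _window_sums(track, g.chrom, pos, n_cols, w)
        rows.append(sums * track.rpm_factor / (w * w))
        names.append(g.name)
        clipped.append(clip)
    values = np.array(rows) if rows else np.zeros((0, n_cols))
    return AnchorMatrix(names, anchor, flank_bp, w, values, 0, np.array(clipped, dtype=bool), dropped)


def scaled_gene_matrix(track: CoverageTrack, gs: GeneSet, n_body_bins: int = 100, flank_bp: int = 4000) -> AnchorMatrix:
    """Metagene matrix: fixed-width upstream flank, gene body rescaled to
    ``n_body_bins`` proportional bins, fixed-width downstream flank."""
    w = track.bin_width
    if flank_bp % w:
        raise ValueError(f"flank_bp {flank_bp} not a multiple of bin_width {w}")
    n_flank = flank_bp // w
    names, rows, clipped, dropped = [], [], [], []
    for g in gs:
        if g.chrom not in track.covered:
            dropped.append(g.name)
            continue
        if g.length < n_body_bins:
            dropped.append(g.name)
            continue
        size = track.chrom_sizes[g.chrom]
        cov = track.covered[g.chrom]

        def window_mean(lo: int, hi: int) -> float:
            p = np.arange(lo, hi)
            ok = (p >= 0) & (p < size)
            s = int(cov[p[ok] // w].sum()) if ok.any() else 0
            return s * track.rpm_factor / (w * (hi - lo)), bool((~ok).any())

        clip = False
        # upstream flank (transcription orientation)
        up, body, down = [], [], []
        if g.strand == "+":
            for j in range(n_flank):
                v, c = window_mean(g.start - flank_bp + j * w, g.start - flank_bp + (j + 1) * w)
                up.append(v)
                clip |= c
            cuts = [g.start + (i * g.length) // n_body_bins for i in range(n_body_bins + 1)]
            for i in range(n_body_bins):
                v, c = window_mean(cuts[i], cuts[i + 1])
                body.append(v)
                clip |= c
            for j in range(n_flank):
                v, c = window_mean(g.end + j * w, g.end + (j + 1) * w)
                down.append(v)
                clip |= c
        else:
            for j in range(n_flank):
                v, c = window_mean(g.end + flank_bp - (j + 1) * w, g.end + flank_bp - j * w)
                up.append(v)
                clip |= c
            cuts = [g.end - (i * g.length) // n_body_bins for i in range(n_body_bins + 1)]
            for i in range(n_body_bins):
                v, c = window_mean(cuts[i + 1], cuts[i])
                body.append(v)
                clip |= c
            for j in range(n_flank):
                v, c = window_mean(g.start - (j + 1) * w, g.start - j * w)
                down.append(v)
                clip |= c
        rows.append(np.array(up + body + down))
        names.append(g.name)
        clipped.append(clip)
    values = np.array(rows) if rows else np.zeros((0, 2 * n_flank + n_body_bins))
    return AnchorMatrix(names, "scaled_body", flank_bp, w, values, n_body_bins, np.array(clipped, dtype=bool), dropped)


def mean_profile(m: AnchorMatrix, gene_subset=None) -> np.ndarray:
    """Column-wise mean density over all rows or a named subset."""
    if gene_subset is None:
        if m.n_genes == 0:
            raise ValueError("empty matrix")
        return m.values.mean(axis=0)
    idx = [m.genes.index(g) for g in gene_subset]
    if not idx:
        raise ValueError("empty gene subset")
    return m.values[idx].mean(axis=0)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom, size in track.chrom_sizes.items():
            vals = track.values(chrom)
            for i, v in enumerate(vals):
                if v != 0:
                    fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, size)}\t{v:.6g}\n")
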