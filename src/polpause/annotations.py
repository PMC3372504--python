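"""Gene-model ingestion, transcript collapsing, isolation filtering and class labels.

All coordinates are 0-based half-open internally (BED convention).  GTF input
is 1-based inclusive and converted on read.  Anchors are strand aware: the
transcription start site (TSS) of a minus-strand gene is its highest genomic
base, and the end of the annotated gene (EAG) its lowest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneModel",
    "GeneSet",
    "read_gene_models",
    "collapse_transcripts",
    "filter_isolated",
    "assign_gene_class",
    "write_bed6",
    "write_filter_log",
]

GENE_CLASSES = ("core_histone", "variant_histone", "other", "unknown")


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit with strand-aware anchors and exon structure."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    transcript_id: str = ""
    exon_starts: tuple[int, ...] = ()
    exon_ends: tuple[int, ...] = ()
    gene_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.name}: exon start/end lists differ in length")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError(f"{self.name}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.name}: exon [{s},{e}) outside [{self.start},{self.end})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: exons unsorted or overlapping")
            prev_end = e
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.name}: unknown gene_class {self.gene_class!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (genomic bp)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def eag(self) -> int:
        """Strand-aware end of annotated gene (genomic bp)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return max(len(self.exon_starts), 1)

    @property
    def intronless(self) -> bool:
        return self.n_exons == 1


@dataclass
class GeneSet:
    """An ordered collection of gene models plus a provenance/filter log."""

    genes: list[GeneModel]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def by_name(self) -> dict[str, GeneModel]:
        return {g.name: g for g in self.genes}

    def log(self, message: str) -> None:
        self.provenance.append(message)


def _parse_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount disagrees with block lists")
            ex_s = tuple(start + o for o in offsets)
            ex_e = tuple(start + o + s for o, s in zip(offsets, sizes))
            genes.append(GeneModel(chrom, start, end, strand, name, name, ex_s, ex_e))
    return genes


def _parse_refflat(path: str) -> list[GeneModel]:
    # UCSC refFlat: geneName txName chrom strand txStart txEnd cdsStart cdsEnd
    #               exonCount exonStarts exonEnds
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 11:
                raise ValueError(f"{path}:{lineno}: refFlat needs 11 fields, got {len(f)}")
            name, tx_id, chrom, strand = f[0], f[1], f[2], f[3]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            start, end = int(f[4]), int(f[5])
            ex_s = tuple(int(x) for x in f[9].rstrip(",").split(","))
            ex_e = tuple(int(x) for x in f[10].rstrip(",").split(","))
            genes.append(GeneModel(chrom, start, end, strand, name, tx_id, ex_s, ex_e))
    return genes


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: str) -> list[GeneModel]:
    # Collect exon features per transcript; 1-based inclusive -> 0-based half-open.
    tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GTF needs 9 fields, got {len(f)}")
            chrom, _, feature, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            if feature != "exon":
                continue
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = dict(_GTF_ATTR.findall(f[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id attribute")
            tid = attrs["transcript_id"]
            rec = tx.setdefault(
                tid, {"chrom": chrom, "strand": strand, "gene": attrs.get("gene_name", attrs["gene_id"]), "exons": []}
            )
            rec["exons"].append((int(start) - 1, int(end)))
    genes = []
    for tid, rec in tx.items():
        exons = sorted(rec["exons"])
        genes.append(
            GeneModel(
                rec["chrom"],
                exons[0][0],
                exons[-1][1],
                rec["strand"],
                rec["gene"],
                tid,
                tuple(s for s, _ in exons),
                tuple(e for _, e in exons),
            )
        )
    return genes


def read_gene_models(path: str, format: str = "bed12") -> GeneSet:
    """Read transcript models from BED12, refFlat or GTF into a :class:`GeneSet`.

    One :class:`GeneModel` per transcript; coordinates are normalised to
    0-based half-open regardless of the input dialect.
    """
    parsers = {"bed12": _parse_bed12, "refflat": _parse_refflat, "gtf": _parse_gtf}
    if format not in parsers:
        raise ValueError(f"unknown annotation format {format!r}")
    genes = parsers[format](path)
    gs = GeneSet(genes)
    gs.log(f"read {len(genes)} transcripts from {path} ({format})")
    return gs


def collapse_transcripts(gs: GeneSet, rule: str = "longest") -> GeneSet:
    """Reduce to one model per gene name.

    ``longest`` keeps the longest transcript; ``union`` merges the
    transcription-unit extent and exon set of all isoforms.  Names that occur
    on more than one chromosome or strand are dropped and logged, since a
    single anchor cannot be defined for them.
    """
    if rule not in ("longest", "union"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    by_name: dict[str, list[GeneModel]] = {}
    for g in gs:
        by_name.setdefault(g.name, []).append(g)
    out = GeneSet([], list(gs.provenance))
    dropped = []
    for name, models in by_name.items():
        locs = {(m.chrom, m.strand) for m in models}
        if len(locs) > 1:
            dropped.append(name)
            continue
        if rule == "longest" or len(models) == 1:
            out.genes.append(max(models, key=lambda m: (m.length, m.transcript_id)))
        else:
            start = min(m.start for m in models)
            end = max(m.end for m in models)
            # merge exon intervals across isoforms
            ivs = sorted((s, e) for m in models for s, e in zip(m.exon_starts, m.exon_ends))
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            m0 = models[0]
            out.genes.append(
                GeneModel(
                    m0.chrom,
                    start,
                    end,
                    m0.strand,
                    name,
                    name,
                    tuple(s for s, _ in merged),
                    tuple(e for _, e in merged),
                    m0.gene_class,
                )
            )
    for name in dropped:
        out.log(f"collapse: dropped {name} (multiple chromosomes/strands)")
    out.log(f"collapse rule={rule}: {len(gs)} transcripts -> {len(out)} genes")
    return out


def nearest_neighbor_distances(gs: GeneSet) -> dict[str, float]:
    """Gap (bp) from each gene's TU interval to the nearest other TU on the
    same chromosome, strand-blind.  Overlapping TUs have distance 0; a gene
    alone on its chromosome gets ``inf``."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gs:
        by_chrom.setdefault(g.chrom, []).append(g)
    dist: dict[str, float] = {}
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        for i, g in enumerate(genes):
            d = float("inf")
            if i > 0:
                left = max(genes[j].end for j in range(i))
                d = min(d, max(0, g.start - left))
            if i < len(genes) - 1:
                d = min(d, max(0, genes[i + 1].start - g.end))
            dist[g.name] = d
    return dist


def filter_isolated(gs: GeneSet, min_distance_bp: int) -> GeneSet:
    """Keep genes at least ``min_distance_bp`` from the nearest other
    transcription unit on the same chromosome (strand-blind); genes with no
    neighbor are kept."""
    if min_distance_bp < 0:
        raise ValueError("min_distance_bp must be >= 0")
    dist = nearest_neighbor_distances(gs)
    out = GeneSet([g for g in gs if dist[g.name] >= min_distance_bp], list(gs.provenance))
    out.log(f"filter_isolated(D={min_distance_bp}): {len(gs)} -> {len(out)} genes")
    return out


def assign_gene_class(
    gs: GeneSet,
    core_list: list[str] | set[str] = (),
    variant_list: list[str] | set[str] = (),
    name_pattern: str | None = None,
) -> GeneSet:
    """Label genes core_histone / variant_histone / other.

    Explicit lists win; an optional regex (e.g. ``^HIST``) marks remaining
    matches core_histone; everything else becomes ``other``.
    """
    core = set(core_list)
    variant = set(variant_list)
    both = core & variant
    if both:
        raise ValueError(f"genes in both class lists: {sorted(both)}")
    pat = re.compile(name_pattern) if name_pattern else None
    out = GeneSet([], list(gs.provenance))
    for g in gs:
        if g.name in core:
            cls = "core_histone"
        elif g.name in variant:
            cls = "variant_histone"
        elif pat and pat.search(g.name):
            cls = "core_histone"
        else:
            cls = "other"
        out.genes.append(replace(g, gene_class=cls))
    n_core = sum(g.gene_class == "core_histone" for g in out)
    out.log(f"assign_gene_class: {n_core} core_histone of {len(out)}")
    return out


def write_bed6(gs: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in gs:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def write_filter_log(gs: GeneSet, kept: GeneSet, path: str) -> None:
    """TSV of gene, nearest-neighbor distance and kept flag."""
    dist = nearest_neighbor_distances(gs)
    kept_names = set(kept.names())
    with open(path, "w") as fh:
        fh.write("gene\tnearest_neighbor_bp\tkept\n")
        for g in gs:
            d = dist[g.name]
            fh.write(f"{g.name}\t{'inf' if d == float('inf') else int(d)}\t{int(g.name in kept_names)}\n")
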