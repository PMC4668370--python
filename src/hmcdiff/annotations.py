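"""Construction of the genomic annotation sets tested for 5-hmC enrichment.

Builds promoters (a fixed window around each transcription start site), CpG
shores (fixed-width flanks of CpG islands with island bases excluded),
flank-extended gene bodies, and wraps externally supplied BED features
(CpG islands, UTRs, exons, introns, transcription-factor binding sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

from .intervals import ChromSizes, GenomicInterval, merge, slop, subtract
from .io import load_gtf_db, read_bed

__all__ = [
    "GeneModel",
    "AnnotationSet",
    "build_promoters",
    "build_shores",
    "extend_genes",
    "load_gene_models",
    "load_bed_annotation",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene: the union span of its transcripts plus all transcript TSSs.

    ``tss`` is the 5' end of the gene body (start on '+', end-1 on '-');
    ``tss_sites`` lists every distinct transcript start, which is what
    promoter construction iterates over.
    """

    gene_id: str
    body: GenomicInterval
    tss_sites: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: body must be stranded")
        if not self.tss_sites:
            object.__setattr__(self, "tss_sites", (self.tss,))

    @property
    def tss(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1


@dataclass(frozen=True)
class AnnotationSet:
    """A named, merged, strand-agnostic set of genomic intervals."""

    name: str
    intervals: Tuple[GenomicInterval, ...]

    @classmethod
    def build(cls, name: str, intervals: Iterable[GenomicInterval]) -> "AnnotationSet":
        return cls(name, tuple(merge(intervals)))

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _promoter_window(
    tss: int, strand: str, chrom: str, sizes: ChromSizes, down: int, up: int,
    strand_aware: bool,
) -> GenomicInterval | None:
    """Window from ``up`` bases upstream of the TSS to ``down`` bases downstream."""
    if strand == "-" and strand_aware:
        start, end = tss + 1 - down, tss + 1 + up
    else:
        start, end = tss - up, tss + down
    start = max(0, start)
    end = min(sizes[chrom], end)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end)


def build_promoters(
    genes: Sequence[GeneModel],
    sizes: ChromSizes,
    down: int = 2000,
    up: int = 500,
    strand_aware: bool = True,
) -> AnnotationSet:
    """Promoter annotation: per transcript TSS, the window reaching ``down``
    bases into the gene and ``up`` bases upstream of it (default 2 kb
    downstream to 500 bp upstream), clamped and merged."""
    if down < 0 or up < 0:
        raise ValueError("promoter extents must be non-negative")
    windows = []
    for g in genes:
        for tss in g.tss_sites:
            w = _promoter_window(tss, g.body.strand, g.body.chrom, sizes, down, up, strand_aware)
            if w is not None:
                windows.append(w)
    return AnnotationSet.build("promoters", windows)


def build_shores(
    islands: AnnotationSet, sizes: ChromSizes, width: int = 2000
) -> AnnotationSet:
    """CpG shores: the ``width``-base flanks of each island, clamped to the
    chromosome, with all island bases subtracted so no base is both island
    and shore."""
    if width <= 0:
        raise ValueError("shore width must be positive")
    flanks: List[GenomicInterval] = []
    for iv in islands.intervals:
        if iv.start > 0:
            flanks.append(GenomicInterval(iv.chrom, max(0, iv.start - width), iv.start))
        end = min(sizes[iv.chrom], iv.end + width)
        if end > iv.end:
            flanks.append(GenomicInterval(iv.chrom, iv.end, end))
    shores = subtract(flanks, list(islands.intervals))
    return AnnotationSet.build("CpG shores", shores)


def extend_genes(
    genes: Sequence[GeneModel], sizes: ChromSizes, flank: int = 2000
) -> Tuple[AnnotationSet, Dict[str, GenomicInterval]]:
    """Gene bodies extended by ``flank`` on both sides.

    Returns the merged annotation plus the unmerged per-gene intervals, which
    stay individually queryable for gene-list intersection.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    per_gene = {g.gene_id: slop(g.body, flank, flank, sizes) for g in genes}
    return AnnotationSet.build("extended genes", per_gene.values()), per_gene


def load_gene_models(gtf_path: str) -> List[GeneModel]:
    """Read gene models from an Ensembl-dialect GTF.

    One model per ``gene_id``: body = union span of its transcripts (the gene
    feature's span when no transcripts are present), converted from 1-based
    closed to 0-based half-open; every distinct transcript TSS is retained.
    """
    db = load_gtf_db(gtf_path)
    spans: Dict[str, List[Tuple[str, int, int, str]]] = {}
    tss: Dict[str, set] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript"):
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        start0, end0 = feat.start - 1, feat.end  # GTF 1-based closed -> half-open
        spans.setdefault(gid, []).append((feat.seqid, start0, end0, feat.strand))
        if feat.featuretype == "transcript":
            tss.setdefault(gid, set()).add(start0 if feat.strand == "+" else end0 - 1)
    genes: List[GeneModel] = []
    for gid, recs in spans.items():
        chroms = {r[0] for r in recs}
        strands = {r[3] for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gid}: features span multiple chromosomes/strands")
        chrom, strand = recs[0][0], recs[0][3]
        body = GenomicInterval(chrom, min(r[1] for r in recs), max(r[2] for r in recs), strand)
        sites = tuple(sorted(tss.get(gid, set()))) or None
        genes.append(GeneModel(gid, body, sites or ()))
    genes.sort(key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    return genes


def load_bed_annotation(bed_path: str, name: str) -> AnnotationSet:
    """Read a BED file as a merged annotation set."""
    return AnnotationSet.build(name, read_bed(bed_path))
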