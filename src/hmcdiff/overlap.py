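"""Replicate-consensus peak sets and base/gene-level overlap comparisons.

A consensus set keeps the bases called as a peak in every member replicate
(strict intersection; a k-of-n mode is available for larger replicate
groups).  Overlap between two consensus sets is reported in bases and as the
fraction of each set covered, and at gene level as a three-way partition of
hydroxymethylated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .annotations import GeneModel
from .intervals import GenomicInterval, Peak, coverage_bases, merge

__all__ = ["ConsensusPeakSet", "consensus", "base_overlap", "gene_overlap"]


@dataclass(frozen=True)
class ConsensusPeakSet:
    """Merged intervals covered by a peak in every member replicate."""

    name: str
    intervals: Tuple[GenomicInterval, ...]

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _as_intervals(replicate: Sequence[Peak | GenomicInterval]) -> List[GenomicInterval]:
    return [p.interval if isinstance(p, Peak) else p for p in replicate]


def _intersect_merged(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Base-level intersection of two merged interval lists."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for iv in a:
        for other in by_chrom.get(iv.chrom, []):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return merge(out)


def consensus(
    replicates: Sequence[Sequence[Peak | GenomicInterval]],
    name: str = "consensus",
    min_replicates: int | None = None,
) -> ConsensusPeakSet:
    """Bases with a called peak in every replicate (or in >= ``min_replicates``
    of them when given), merged."""
    if not replicates:
        raise ValueError("consensus requires at least one replicate")
    merged = [merge(_as_intervals(rep)) for rep in replicates]
    if min_replicates is None or min_replicates >= len(replicates):
        current = merged[0]
        for other in merged[1:]:
            current = _intersect_merged(current, other)
        return ConsensusPeakSet(name, tuple(current))
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    # k-of-n: sweep over coverage depth of the merged replicate coverages
    events: Dict[str, List[Tuple[int, int]]] = {}
    for rep in merged:
        for iv in rep:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events.setdefault(iv.chrom, []).append((iv.end, -1))
    out: List[GenomicInterval] = []
    for chrom, evs in events.items():
        evs.sort()
        depth, open_start = 0, None
        for pos, delta in evs:
            new_depth = depth + delta
            if depth < min_replicates <= new_depth:
                open_start = pos
            elif depth >= min_replicates > new_depth and open_start is not None:
                if pos > open_start:
                    out.append(GenomicInterval(chrom, open_start, pos))
                open_start = None
            depth = new_depth
    return ConsensusPeakSet(name, tuple(merge(out)))


def base_overlap(
    a: ConsensusPeakSet, b: ConsensusPeakSet
) -> Tuple[int, float, float]:
    """Bases covered in both sets, and that count as a fraction of each set's
    coverage (NaN when a set is empty)."""
    inter = _intersect_merged(list(a.intervals), list(b.intervals))
    shared = coverage_bases(inter)
    cov_a, cov_b = a.total_bases(), b.total_bases()
    frac_a = shared / cov_a if cov_a else float("nan")
    frac_b = shared / cov_b if cov_b else float("nan")
    return shared, frac_a, frac_b


def _genes_hit(genes: Sequence[GeneModel], peak_set: ConsensusPeakSet) -> Set[str]:
    trees: Dict[str, IntervalTree] = {}
    for iv in peak_set.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    hit = set()
    for g in genes:
        tree = trees.get(g.body.chrom)
        if tree is not None and tree.overlap(g.body.start, g.body.end):
            hit.add(g.gene_id)
    return hit


def gene_overlap(
    genes: Sequence[GeneModel], a: ConsensusPeakSet, b: ConsensusPeakSet
) -> Tuple[int, int, int]:
    """Three-way partition of hydroxymethylated genes between two consensus
    sets: (only in a, only in b, in both).  A gene counts for a set when the
    set intersects its unextended body by >=1 base."""
    hit_a, hit_b = _genes_hit(genes, a), _genes_hit(genes, b)
    return len(hit_a - hit_b), len(hit_b - hit_a), len(hit_a & hit_b)
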