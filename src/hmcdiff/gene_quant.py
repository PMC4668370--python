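"""Gene-level 5-hmC quantification.

Counts aligned tags over gene bodies for genes carrying a called peak,
normalizes to tags per base of gene (the per-gene 5-hmC density), assigns
genes to density percentile bins, and computes metagene coverage profiles
(feature bodies rescaled to a common bin axis with fixed-width flanks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .annotations import GeneModel
from .intervals import GenomicInterval, Peak

__all__ = [
    "TagAlignment",
    "GeneHmcRecord",
    "BIN_LABELS",
    "genes_with_peaks",
    "count_tags_per_gene",
    "bin_by_percentile",
    "metagene_profile",
]


@dataclass(frozen=True)
class TagAlignment:
    """A single aligned sequencing tag."""

    interval: GenomicInterval


@dataclass(frozen=True)
class GeneHmcRecord:
    """Per-gene tag count, length, density, and (optionally) percentile bin."""

    gene_id: str
    tag_count: int
    gene_length: int
    bin: str | None = None

    @property
    def density(self) -> float:
        return self.tag_count / self.gene_length


BIN_LABELS = ("P0_25", "P25_75", "P75_98", "P98_100")


def genes_with_peaks(
    genes: Sequence[GeneModel], peaks: Sequence[Peak], flank: int = 2000
) -> Set[str]:
    """Gene ids whose flank-extended body overlaps at least one peak by >=1
    base (the rule used to build hydroxymethylated gene lists)."""
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        iv = p.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    hit: Set[str] = set()
    for g in genes:
        tree = trees.get(g.body.chrom)
        if tree is None:
            continue
        if tree.overlap(max(0, g.body.start - flank), g.body.end + flank):
            hit.add(g.gene_id)
    return hit


def count_tags_per_gene(
    tags: Sequence[TagAlignment],
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
) -> List[GeneHmcRecord]:
    """Tag counts and densities for genes carrying a called peak.

    Only genes whose unextended body overlaps >=1 peak are emitted.  A tag
    counts toward a gene when it overlaps the gene body; a tag overlapping
    more than one emitted gene is ambiguous and contributes to none
    (union-mode counting).
    """
    with_peak = genes_with_peaks(genes, peaks, flank=0)
    emitted = [g for g in genes if g.gene_id in with_peak]
    gene_trees: Dict[str, IntervalTree] = {}
    for g in emitted:
        gene_trees.setdefault(g.body.chrom, IntervalTree()).addi(
            g.body.start, g.body.end, g.gene_id
        )
    counts: Dict[str, int] = {g.gene_id: 0 for g in emitted}
    for t in tags:
        iv = t.interval
        tree = gene_trees.get(iv.chrom)
        if tree is None:
            continue
        hits = {h.data for h in tree.overlap(iv.start, iv.end)}
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return [
        GeneHmcRecord(g.gene_id, counts[g.gene_id], len(g.body)) for g in emitted
    ]


def bin_by_percentile(
    records: Sequence[GeneHmcRecord], cuts: Tuple[float, ...] = (25, 75, 98)
) -> List[GeneHmcRecord]:
    """Assign each gene a density percentile bin (default 0-25, 25-75, 75-98,
    98-100).

    A gene of ascending-density rank r out of n sits at percentile 100*r/n;
    bins have inclusive upper edges.  Ties are broken by gene id so the
    assignment is deterministic.
    """
    if len(records) < 4:
        raise ValueError("percentile binning needs at least 4 records")
    if list(cuts) != sorted(cuts) or not all(0 < c < 100 for c in cuts):
        raise ValueError("cuts must be increasing and inside (0, 100)")
    edges = list(cuts) + [100.0]
    if len(edges) == 4:
        labels = list(BIN_LABELS)
    else:
        lo = [0.0] + list(cuts)
        labels = [f"P{int(a)}_{int(b)}" for a, b in zip(lo, edges)]
    n = len(records)
    ordered = sorted(records, key=lambda r: (r.density, r.gene_id))
    out = []
    for rank, rec in enumerate(ordered, start=1):
        pct = 100.0 * rank / n
        for label, edge in zip(labels, edges):
            if pct <= edge + 1e-12:
                out.append(GeneHmcRecord(rec.gene_id, rec.tag_count, rec.gene_length, label))
                break
    out.sort(key=lambda r: r.gene_id)
    return out


class _CoverageIndex:
    """Integrated multiset coverage of a tag set, per chromosome.

    F(x) = total tag bases in (-inf, x), counted with multiplicity; piecewise
    linear between coverage-change points, so the tag mass over any window
    [a, b) is F(b) - F(a) with two interpolated lookups.
    """

    def __init__(self, tags: Sequence[TagAlignment]):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for t in tags:
            iv = t.interval
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._tables: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            events = np.concatenate([starts, ends])
            deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
            order = np.argsort(events, kind="stable")
            pos = events[order].astype(float)
            depth = np.cumsum(deltas[order]).astype(float)
            # collapse duplicate positions, keep last depth at each
            keep = np.append(pos[1:] != pos[:-1], True)
            pos, depth = pos[keep], depth[keep]
            f = np.concatenate([[0.0], np.cumsum(depth[:-1] * np.diff(pos))])
            self._tables[chrom] = (pos, depth, f)

    def integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        if chrom not in self._tables:
            return np.zeros(np.shape(x), dtype=float)
        pos, depth, f = self._tables[chrom]
        idx = np.searchsorted(pos, x, side="right") - 1
        safe = np.maximum(idx, 0)
        val = f[safe] + depth[safe] * (x - pos[safe])
        return np.where(idx >= 0, val, 0.0)

    def window_mass(self, chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.integral(chrom, b) - self.integral(chrom, a)


def metagene_profile(
    tags: Sequence[TagAlignment],
    features: Sequence[GenomicInterval],
    body_bins: int = 100,
    flank: int = 2000,
    flank_bins: int = 20,
) -> np.ndarray:
    """Average tag coverage around a feature set, body rescaled to a common axis.

    Each feature contributes ``flank_bins`` fixed-width upstream bins, its
    body rescaled into ``body_bins`` bins, and ``flank_bins`` downstream bins;
    minus-strand features are reversed so bin 0 is always the 5' flank end.
    The returned vector is mean per-bin coverage in tags per million aligned
    tags per base.
    """
    if not features:
        raise ValueError("no features supplied")
    if not tags:
        return np.zeros(2 * flank_bins + body_bins)
    index = _CoverageIndex(tags)
    total_tags = len(tags)
    n_bins = 2 * flank_bins + body_bins
    acc = np.zeros(n_bins)
    for feat in features:
        up = np.linspace(feat.start - flank, feat.start, flank_bins + 1)
        body = np.linspace(feat.start, feat.end, body_bins + 1)
        down = np.linspace(feat.end, feat.end + flank, flank_bins + 1)
        edges = np.concatenate([up[:-1], body[:-1], down])
        mass = index.window_mass(feat.chrom, edges[:-1], edges[1:])
        widths = np.diff(edges)
        per_bp = mass / widths
        if feat.strand == "-":
            per_bp = per_bp[::-1]
        acc += per_bp
    return acc / len(features) * 1e6 / total_tags
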