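"""Genomic interval primitives and arithmetic.

All coordinates are 0-based, half-open (BED convention).  The types here are
the substrate for every downstream computation: MACS-style peaks carrying tag
counts, interval merging/extension, base-level coverage, and genome-wide
random shuffling of peaks used to build permutation null distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "Peak",
    "intersect_length",
    "merge",
    "slop",
    "shuffle",
    "coverage_bases",
]


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bases). Lengths must be positive."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, chrom: str) -> int:
        try:
            return self.entries[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    @property
    def total(self) -> int:
        """Total genome length in bases."""
        return sum(self.entries.values())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the number of sequencing tags in it.

    ``density`` is tags per base of the peak, the quantity the tag-weighted
    enrichment statistic accumulates over peak/annotation intersections.
    """

    interval: GenomicInterval
    tags: float

    def __post_init__(self) -> None:
        if self.tags < 0:
            raise ValueError("tag count must be non-negative")

    @property
    def density(self) -> float:
        return self.tags / len(self.interval)


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Collapse intervals into a sorted, disjoint set covering the same bases.

    Strand is discarded (merged intervals are unstranded); intervals that
    touch end-to-start are joined.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: List[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def slop(iv: GenomicInterval, left: int, right: int, sizes: ChromSizes) -> GenomicInterval:
    """Extend an interval by ``left``/``right`` bases, clamped to the chromosome."""
    if left < 0 or right < 0:
        raise ValueError("slop distances must be non-negative")
    length = sizes[iv.chrom]
    return GenomicInterval(
        iv.chrom, max(0, iv.start - left), min(length, iv.end + right), iv.strand
    )


def subtract(intervals: Sequence[GenomicInterval], remove: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Bases of ``intervals`` not covered by ``remove`` (both need not be merged)."""
    removed = merge(remove)
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in removed:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: List[GenomicInterval] = []
    for iv in merge(intervals):
        cuts = by_chrom.get(iv.chrom, [])
        pos = iv.start
        for s, e in cuts:
            if e <= pos or s >= iv.end:
                continue
            if s > pos:
                out.append(GenomicInterval(iv.chrom, pos, min(s, iv.end)))
            pos = max(pos, e)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def coverage_bases(peaks: Iterable[Peak | GenomicInterval]) -> int:
    """Number of distinct bases covered by the union of peak intervals."""
    ivs = [p.interval if isinstance(p, Peak) else p for p in peaks]
    return sum(len(iv) for iv in merge(ivs))


def shuffle(
    peaks: Sequence[Peak],
    sizes: ChromSizes,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> List[Peak]:
    """Randomly relocate peaks across the genome, preserving length and tags.

    Each peak is placed on a chromosome drawn with probability proportional
    to chromosome length among the chromosomes long enough to contain it,
    then given a uniform start such that it fits entirely.  Shuffled peaks
    may overlap one another.  Identical seeds give identical placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(sizes)
    lengths = np.array([sizes[c] for c in names], dtype=np.int64)
    n = len(peaks)
    if n == 0:
        return []
    peak_lens = np.array([len(p.interval) for p in peaks], dtype=np.int64)
    max_len = int(lengths.max())
    too_long = peak_lens > max_len
    if too_long.any():
        bad = peaks[int(np.argmax(too_long))]
        raise ValueError(
            f"peak of length {len(bad.interval)} exceeds every chromosome"
        )
    out: List[Peak] = []
    if (peak_lens <= lengths.min()).all():
        # fast path: every peak fits on every chromosome
        probs = lengths / lengths.sum()
        chrom_idx = rng.choice(len(names), size=n, p=probs)
        span = lengths[chrom_idx] - peak_lens + 1
        starts = (rng.random(n) * span).astype(np.int64)
        for p, ci, s in zip(peaks, chrom_idx, starts):
            iv = p.interval
            out.append(Peak(GenomicInterval(names[ci], int(s), int(s) + len(iv), iv.strand), p.tags))
        return out
    for p in peaks:
        plen = len(p.interval)
        ok = lengths >= plen
        probs = np.where(ok, lengths, 0).astype(float)
        probs /= probs.sum()
        ci = int(rng.choice(len(names), p=probs))
        s = int(rng.integers(0, lengths[ci] - plen + 1))
        out.append(Peak(GenomicInterval(names[ci], s, s + plen, p.interval.strand), p.tags))
    return out
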