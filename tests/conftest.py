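"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pytest

from hmcdiff import AnnotationSet, ChromSizes, GenomicInterval, Peak


@pytest.fixture
def small_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


def random_micro_instance(
    rng: np.random.Generator,
    genome_len: int = 10_000,
    max_peaks: int = 20,
    max_ann: int = 10,
) -> Tuple[ChromSizes, List[Peak], AnnotationSet]:
    """A tiny random genome with peaks and an annotation, for oracle checks."""
    sizes = ChromSizes({"chrA": genome_len, "chrB": genome_len // 2})
    chroms = ["chrA", "chrB"]
    peaks = []
    for _ in range(int(rng.integers(1, max_peaks + 1))):
        chrom = chroms[int(rng.integers(0, 2))]
        length = int(rng.integers(5, 500))
        start = int(rng.integers(0, sizes[chrom] - length))
        peaks.append(Peak(GenomicInterval(chrom, start, start + length), int(rng.integers(0, 100))))
    ann_ivs = []
    for _ in range(int(rng.integers(1, max_ann + 1))):
        chrom = chroms[int(rng.integers(0, 2))]
        length = int(rng.integers(10, 2000))
        start = int(rng.integers(0, sizes[chrom] - length))
        ann_ivs.append(GenomicInterval(chrom, start, start + length))
    return sizes, peaks, AnnotationSet.build("micro", ann_ivs)


def brute_force_observed(peaks: Sequence[Peak], annotation: AnnotationSet) -> float:
    """Per-base accumulation of peak density over annotation bases."""
    ann_bases: Dict[str, Set[int]] = {}
    for iv in annotation.intervals:
        ann_bases.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    total = 0.0
    for p in peaks:
        bases = ann_bases.get(p.interval.chrom, set())
        for pos in range(p.interval.start, p.interval.end):
            if pos in bases:
                total += p.density
    return total


def brute_force_coverage(intervals: Sequence[GenomicInterval]) -> int:
    covered: Set[Tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            covered.add((iv.chrom, pos))
    return len(covered)


def exact_wilcoxon_oracle(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Exhaustive-enumeration Wilcoxon rank-sum (tie-free samples only).

    Two-sided p = probability, over all rank assignments, of a rank sum at
    least as far from its null mean as the observed one.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, nx = len(pooled), len(x)
    mean = nx * (n + 1) / 2
    dev = abs(w_obs - mean)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), nx):
        total += 1
        if abs(sum(combo) - mean) >= dev - 1e-9:
            count += 1
    return float(w_obs), count / total


def chi2_oracle(table: np.ndarray) -> float:
    """Textbook Pearson chi-squared statistic from a contingency table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
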