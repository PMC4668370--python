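"""Tag-weighted permutation enrichment of peaks over genomic annotations.

The observed statistic is the total number of sequencing tags falling over an
annotation, computed per peak as (length of the peak/annotation intersection)
x (the peak's tags-per-base density) and summed genome-wide.  The null is
built by shuffling the peaks across the genome (lengths and tag counts
preserved) and recomputing the statistic; the enrichment ratio is observed
over the mean of the null, and the empirical p-value uses an add-one
pseudocount so it is never zero (floor 1/(n_shuffles+1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .annotations import AnnotationSet
from .intervals import ChromSizes, Peak, shuffle

__all__ = [
    "EnrichmentResult",
    "observed_tags",
    "expected_tags",
    "enrichment_test",
    "average_replicates",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation-test summary for one annotation."""

    annotation: str
    observed: float
    expected: float
    expected_sd: float
    enrichment: float  # observed / expected; NaN when expected == 0
    p_empirical: float  # one-sided, enrichment tail, add-one estimator
    p_depletion: float  # one-sided, depletion tail
    n_shuffles: int


class _AnnotationIndex:
    """Per-chromosome prefix sums over a merged annotation, so the overlap of
    any interval with the annotation union is two searchsorted lookups."""

    def __init__(self, annotation: AnnotationSet):
        self.by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per: Dict[str, List[Tuple[int, int]]] = {}
        for iv in annotation.intervals:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in per.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            lens = ends - starts
            cum_before = np.cumsum(lens) - lens
            self.by_chrom[chrom] = (starts, ends, cum_before)

    def _prefix(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Annotation bases on ``chrom`` strictly before position x."""
        starts, ends, cum_before = self.by_chrom[chrom]
        idx = np.searchsorted(starts, x, side="right") - 1
        safe = np.maximum(idx, 0)
        within = np.minimum(x - starts[safe], ends[safe] - starts[safe])
        return np.where(idx >= 0, cum_before[safe] + within, 0)

    def overlap(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if chrom not in self.by_chrom:
            return np.zeros(len(starts), dtype=np.int64)
        return self._prefix(chrom, ends) - self._prefix(chrom, starts)


def _grouped_arrays(peaks: Sequence[Peak]) -> Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    groups: Dict[str, List[Peak]] = {}
    for p in peaks:
        groups.setdefault(p.interval.chrom, []).append(p)
    out = {}
    for chrom, ps in groups.items():
        starts = np.array([p.interval.start for p in ps], dtype=np.int64)
        ends = np.array([p.interval.end for p in ps], dtype=np.int64)
        dens = np.array([p.density for p in ps], dtype=float)
        out[chrom] = (starts, ends, dens)
    return out


def observed_tags(peaks: Sequence[Peak], annotation: AnnotationSet) -> float:
    """Total sequencing tags over the annotation:
    sum over peaks of (intersection length) x (peak tags per base)."""
    index = _AnnotationIndex(annotation)
    total = 0.0
    for chrom, (starts, ends, dens) in _grouped_arrays(peaks).items():
        total += float(np.dot(index.overlap(chrom, starts, ends), dens))
    return total


def expected_tags(
    peaks: Sequence[Peak],
    annotation: AnnotationSet,
    sizes: ChromSizes,
    n_shuffles: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> Tuple[float, float, np.ndarray]:
    """Null distribution of the observed statistic under genome-wide shuffling.

    Returns (mean, sd, null_samples).  Each shuffle iteration is seeded from
    an independent child of the master seed, so runs are reproducible and the
    iterations independent.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_shuffles)
    index = _AnnotationIndex(annotation)
    null = np.empty(n_shuffles, dtype=float)
    for i, child in enumerate(children):
        shuffled = shuffle(peaks, sizes, np.random.default_rng(child))
        total = 0.0
        for chrom, (starts, ends, dens) in _grouped_arrays(shuffled).items():
            total += float(np.dot(index.overlap(chrom, starts, ends), dens))
        null[i] = total
    return float(null.mean()), float(null.std()), null


def enrichment_test(
    peaks: Sequence[Peak],
    annotation: AnnotationSet,
    sizes: ChromSizes,
    n_shuffles: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> EnrichmentResult:
    """Observed/expected enrichment ratio plus add-one empirical p-values."""
    obs = observed_tags(peaks, annotation)
    mean, sd, null = expected_tags(peaks, annotation, sizes, n_shuffles, seed)
    p_enrich = (1 + int((null >= obs).sum())) / (1 + n_shuffles)
    p_deplete = (1 + int((null <= obs).sum())) / (1 + n_shuffles)
    ratio = obs / mean if mean > 0 else float("nan")
    return EnrichmentResult(
        annotation=annotation.name,
        observed=obs,
        expected=mean,
        expected_sd=sd,
        enrichment=ratio,
        p_empirical=p_enrich,
        p_depletion=p_deplete,
        n_shuffles=n_shuffles,
    )


def average_replicates(results: Sequence[EnrichmentResult]) -> Tuple[float, float]:
    """Mean and standard deviation of enrichment ratios across biological
    replicates of the same annotation (sd 0 for a single replicate)."""
    if not results:
        raise ValueError("no replicates supplied")
    names = {r.annotation for r in results}
    if len(names) > 1:
        raise ValueError(f"replicates mix annotations: {sorted(names)}")
    vals = np.array([r.enrichment for r in results], dtype=float)
    if len(vals) == 1:
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))
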