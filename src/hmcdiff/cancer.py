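"""Tumor/normal differential 5-hmC calls and expression concordance.

Genes are called as losing 5-hmC when the normal-sample consensus hits their
body but the tumor consensus does not (gaining mirrored).  Expression
concordance is then counted with per-gene Wilcoxon rank-sum tests on
tumor vs normal expression cohorts, Bonferroni-corrected across the called
genes, with direction taken from the median difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotations import GeneModel
from .overlap import ConsensusPeakSet, _genes_hit

__all__ = [
    "DifferentialHmcCall",
    "ConcordanceSummary",
    "call_hmc_change",
    "wilcoxon_rank_sum",
    "bonferroni",
    "concordance_counts",
]


@dataclass(frozen=True)
class DifferentialHmcCall:
    gene_id: str
    direction: str  # "gain" or "loss"

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class ConcordanceSummary:
    """How many 5-hmC loss/gain genes show a concordant expression change."""

    n_loss_total: int
    n_loss_expr_down: int
    n_gain_total: int
    n_gain_expr_up: int
    n_missing_expression: int = 0

    def __post_init__(self) -> None:
        if self.n_loss_expr_down > self.n_loss_total:
            raise ValueError("concordant loss count exceeds loss total")
        if self.n_gain_expr_up > self.n_gain_total:
            raise ValueError("concordant gain count exceeds gain total")


def call_hmc_change(
    genes: Sequence[GeneModel],
    normal_consensus: ConsensusPeakSet,
    tumor_consensus: ConsensusPeakSet,
) -> List[DifferentialHmcCall]:
    """Loss: gene body hit by the normal consensus only; gain: by the tumor
    consensus only.  Genes hit by both or neither are uncalled."""
    hit_n = _genes_hit(genes, normal_consensus)
    hit_t = _genes_hit(genes, tumor_consensus)
    calls = [DifferentialHmcCall(g, "loss") for g in sorted(hit_n - hit_t)]
    calls += [DifferentialHmcCall(g, "gain") for g in sorted(hit_t - hit_n)]
    return calls


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (rank sum of x in the pooled ranking, two-sided p).  Uses exact
    enumeration when the pooled sample is small (<= 12) and tie-free,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rank_sum = float(ranks[:nx].sum())
    if np.all(pooled == pooled[0]):
        return rank_sum, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return rank_sum, float(min(1.0, res.pvalue))


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """Bonferroni adjustment: min(1, m * p) with m the number of tests."""
    m = len(p_values)
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def concordance_counts(
    calls: Sequence[DifferentialHmcCall],
    tumor_expr: Mapping[str, Sequence[float]],
    normal_expr: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> ConcordanceSummary:
    """Count called genes whose expression change is concordant with their
    5-hmC change.

    For every called gene with expression in both cohorts, a Wilcoxon
    rank-sum test compares tumor vs normal expression; p-values are
    Bonferroni-corrected across the tested genes.  A loss gene "lost
    expression" when its adjusted p <= alpha and the tumor median is below
    the normal median; gains mirrored.
    """
    tested: List[DifferentialHmcCall] = []
    missing = 0
    for c in calls:
        if c.gene_id in tumor_expr and c.gene_id in normal_expr:
            tested.append(c)
        else:
            missing += 1
    raw_p: List[float] = []
    med_diff: List[float] = []
    for c in tested:
        t = np.asarray(tumor_expr[c.gene_id], dtype=float)
        n = np.asarray(normal_expr[c.gene_id], dtype=float)
        _, p = wilcoxon_rank_sum(t, n)
        raw_p.append(p)
        med_diff.append(float(np.median(t) - np.median(n)))
    adj = bonferroni(raw_p)
    n_loss = sum(1 for c in tested if c.direction == "loss")
    n_gain = sum(1 for c in tested if c.direction == "gain")
    loss_down = sum(
        1
        for c, p, d in zip(tested, adj, med_diff)
        if c.direction == "loss" and p <= alpha and d < 0
    )
    gain_up = sum(
        1
        for c, p, d in zip(tested, adj, med_diff)
        if c.direction == "gain" and p <= alpha and d > 0
    )
    return ConcordanceSummary(n_loss, loss_down, n_gain, gain_up, missing)
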