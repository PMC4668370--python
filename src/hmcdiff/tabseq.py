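"""TAB-seq / bisulfite clone-count quantification of cytosine states.

Standard bisulfite conversion leaves both 5-mC and 5-hmC reading as C, while
TET-assisted bisulfite (TAB) conversion leaves only 5-hmC reading as C.
Per CpG, the C fraction under TAB therefore estimates %5-hmC directly, the
bisulfite C fraction estimates %5-mC + %5-hmC, and the three states are
recovered by subtraction (with a clamp at zero for sampling noise).
Two conditions are compared by a Pearson chi-squared test on pooled clone
counts.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TabSeqSite",
    "ModificationEstimate",
    "site_modification",
    "compare_conditions",
    "read_tabseq_table",
    "write_site_estimates",
]

MIN_CLONES = 16  # minimum clones per treatment for a site to be quantified


@dataclass(frozen=True)
class TabSeqSite:
    """Clone counts at one CpG under one condition.

    ``bs_c``/``bs_t``: clones reading C/T after plain bisulfite treatment;
    ``tab_c``/``tab_t``: after TET oxidation followed by bisulfite.
    """

    chrom: str
    position: int
    condition: str
    bs_c: int
    bs_t: int
    tab_c: int
    tab_t: int

    def __post_init__(self) -> None:
        if min(self.bs_c, self.bs_t, self.tab_c, self.tab_t) < 0:
            raise ValueError("clone counts must be non-negative")

    @property
    def bs_total(self) -> int:
        return self.bs_c + self.bs_t

    @property
    def tab_total(self) -> int:
        return self.tab_c + self.tab_t


@dataclass(frozen=True)
class ModificationEstimate:
    """Percent 5-hmC / 5-mC / unmodified C at a site; sums to 100."""

    pct_5hmC: float
    pct_5mC: float
    pct_C: float
    clamped: bool = False  # True when sampling noise pushed 5-mC below 0

    def __post_init__(self) -> None:
        total = self.pct_5hmC + self.pct_5mC + self.pct_C
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, not 100")


class LowCoverageError(ValueError):
    """Raised when a site has fewer clones than the quantification floor."""


def site_modification(site: TabSeqSite, min_clones: int = MIN_CLONES) -> ModificationEstimate:
    """Percent C / 5-mC / 5-hmC at one CpG from its clone counts.

    %5-hmC = 100 * TAB C fraction; %5-mC = 100 * (bisulfite C fraction -
    TAB C fraction), clamped at 0; %C is the remainder.
    """
    if site.bs_total < min_clones or site.tab_total < min_clones:
        raise LowCoverageError(
            f"{site.chrom}:{site.position} ({site.condition}): "
            f"bs={site.bs_total}, tab={site.tab_total} clones < floor {min_clones}"
        )
    f_bs = site.bs_c / site.bs_total
    f_tab = site.tab_c / site.tab_total
    pct_5hmc = 100.0 * f_tab
    raw_5mc = 100.0 * (f_bs - f_tab)
    clamped = raw_5mc < 0
    if clamped:
        warnings.warn(
            f"{site.chrom}:{site.position}: TAB C fraction exceeds bisulfite "
            "C fraction (sampling noise); clamping %5-mC to 0"
        )
    pct_5mc = max(0.0, raw_5mc)
    pct_c = max(0.0, 100.0 - pct_5hmc - pct_5mc)  # guard float residue at the boundary
    return ModificationEstimate(pct_5hmc, pct_5mc, pct_c, clamped)


def compare_conditions(
    sites: Sequence[TabSeqSite],
    condition_a: str,
    condition_b: str,
    channel: str = "tab",
    min_clones: int = MIN_CLONES,
    yates: bool = False,
) -> Tuple[float, int, float]:
    """Chi-squared comparison of two conditions on pooled clone counts.

    Clone C/T calls from all quantifiable CpGs are pooled per condition into
    a 2x2 table in the chosen channel ("tab" tests 5-hmC; "bs" tests total
    modification) and compared by Pearson chi-squared with df 1.  A zero
    table margin yields (0, 1, p=1) with a warning.
    """
    if channel not in ("tab", "bs"):
        raise ValueError("channel must be 'tab' or 'bs'")
    counts = {condition_a: [0, 0], condition_b: [0, 0]}
    seen = {condition_a: 0, condition_b: 0}
    for s in sites:
        if s.condition not in counts:
            continue
        if s.bs_total < min_clones or s.tab_total < min_clones:
            continue
        c, t = (s.tab_c, s.tab_t) if channel == "tab" else (s.bs_c, s.bs_t)
        counts[s.condition][0] += c
        counts[s.condition][1] += t
        seen[s.condition] += 1
    if not (seen[condition_a] and seen[condition_b]):
        raise ValueError("need at least one quantifiable site per condition")
    table = np.array([counts[condition_a], counts[condition_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in pooled clone-count table; reporting p = 1")
        return 0.0, 1, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), int(df), float(p)


def read_tabseq_table(path: str | os.PathLike) -> List[TabSeqSite]:
    """Read a clone-count TSV with columns
    chrom, pos, condition, treatment (bs|tab), n_C, n_T (one row per
    site/condition/treatment) into per-site records."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "condition", "treatment", "n_C", "n_T"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    sites: Dict[Tuple[str, int, str], Dict[str, Tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.condition))
        treatment = str(row.treatment)
        if treatment not in ("bs", "tab"):
            raise ValueError(f"{path}: unknown treatment {treatment!r}")
        sites.setdefault(key, {})[treatment] = (int(row.n_C), int(row.n_T))
    out = []
    for (chrom, pos, cond), tr in sorted(sites.items()):
        bs = tr.get("bs", (0, 0))
        tab = tr.get("tab", (0, 0))
        out.append(TabSeqSite(chrom, pos, cond, bs[0], bs[1], tab[0], tab[1]))
    return out


def write_site_estimates(
    sites: Sequence[TabSeqSite], path: str | os.PathLike, min_clones: int = MIN_CLONES
) -> pd.DataFrame:
    """Per-site estimates as TSV; low-coverage sites flagged, not estimated."""
    rows = []
    for s in sites:
        row = {
            "chrom": s.chrom,
            "pos": s.position,
            "condition": s.condition,
            "bs_total": s.bs_total,
            "tab_total": s.tab_total,
        }
        try:
            est = site_modification(s, min_clones)
            row.update(
                pct_5hmC=est.pct_5hmC, pct_5mC=est.pct_5mC, pct_C=est.pct_C,
                low_coverage=False,
            )
        except LowCoverageError:
            row.update(pct_5hmC=np.nan, pct_5mC=np.nan, pct_C=np.nan, low_coverage=True)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
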