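"""Integration of gene expression with gene-level 5-hmC density bins.

Classifies genes as up/down/unchanged from a differential-expression table,
summarizes expression (FPKM) per 5-hmC percentile bin, tests the association
between bin membership and expression class by Pearson chi-squared, and
reports per-bin median log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .gene_quant import BIN_LABELS, GeneHmcRecord

__all__ = [
    "ExpressionRecord",
    "classify_expression",
    "expression_by_hmc_bin",
    "bin_class_association",
    "median_fold_change_by_bin",
]

DE_CLASSES = ("up", "down", "unchanged")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression summary: FPKM, log2 fold change, FDR q-value and
    the resulting differential-expression class."""

    gene_id: str
    fpkm: float
    log2fc: float
    q_value: float
    de_class: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value outside [0,1]: {self.q_value}")
        if self.de_class not in DE_CLASSES:
            raise ValueError(f"unknown class {self.de_class!r}")


def classify_expression(
    de_table: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    fpkm_col: str = "fpkm",
) -> List[ExpressionRecord]:
    """Call genes up/down/unchanged from a differential-expression table.

    Requires columns ``gene_id``, ``log2fc``, ``q_value`` and an FPKM column.
    up: log2fc >= min_abs_log2fc and q <= q_max; down mirrored; else
    unchanged.
    """
    if de_table["gene_id"].duplicated().any():
        dup = de_table["gene_id"][de_table["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id in expression table: {dup!r}")
    out = []
    for row in de_table.itertuples(index=False):
        lfc, q = float(getattr(row, "log2fc")), float(getattr(row, "q_value"))
        if q <= q_max and lfc >= min_abs_log2fc:
            cls = "up"
        elif q <= q_max and lfc <= -min_abs_log2fc:
            cls = "down"
        else:
            cls = "unchanged"
        out.append(
            ExpressionRecord(
                str(getattr(row, "gene_id")), float(getattr(row, fpkm_col)), lfc, q, cls
            )
        )
    return out


def _join(
    records: Sequence[GeneHmcRecord], expr: Sequence[ExpressionRecord]
) -> pd.DataFrame:
    """Inner-join 5-hmC records with expression on gene id; attaches bin."""
    rec_df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "bin": [r.bin for r in records],
            "density": [r.density for r in records],
        }
    )
    if rec_df["bin"].isna().any():
        raise ValueError("records must be binned before integration")
    expr_df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in expr],
            "fpkm": [e.fpkm for e in expr],
            "log2fc": [e.log2fc for e in expr],
            "de_class": [e.de_class for e in expr],
        }
    )
    joined = rec_df.merge(expr_df, on="gene_id", how="inner")
    joined.attrs["n_hmc_only"] = len(rec_df) - len(joined)
    joined.attrs["n_expr_only"] = len(expr_df) - len(joined)
    return joined


def expression_by_hmc_bin(
    records: Sequence[GeneHmcRecord], expr: Sequence[ExpressionRecord]
) -> pd.DataFrame:
    """Per-bin expression summary: gene count, median FPKM and quartiles.

    Bins are ordered from lowest to highest 5-hmC density; bins empty after
    the join are flagged with n = 0 and NaN summaries.
    """
    joined = _join(records, expr)
    if joined.empty:
        raise ValueError("no genes shared between 5-hmC records and expression")
    bins = [b for b in BIN_LABELS if b in set(joined["bin"])] or sorted(set(joined["bin"]))
    order = list(BIN_LABELS) if set(joined["bin"]) <= set(BIN_LABELS) else bins
    rows = []
    for b in order:
        grp = joined.loc[joined["bin"] == b, "fpkm"]
        rows.append(
            {
                "bin": b,
                "n": len(grp),
                "median_fpkm": grp.median() if len(grp) else np.nan,
                "q1_fpkm": grp.quantile(0.25) if len(grp) else np.nan,
                "q3_fpkm": grp.quantile(0.75) if len(grp) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update(joined.attrs)
    return out


def bin_class_association(
    records: Sequence[GeneHmcRecord], expr: Sequence[ExpressionRecord]
) -> Tuple[pd.DataFrame, float, int, float, pd.DataFrame]:
    """Pearson chi-squared test of 5-hmC bin vs expression class.

    Returns (observed table, chi2, df, p, expected table).  Rows or columns
    that are entirely zero are dropped (with a warning) before testing and
    the degrees of freedom adjusted accordingly.
    """
    joined = _join(records, expr)
    if joined.empty:
        raise ValueError("no genes shared between 5-hmC records and expression")
    bin_order = [b for b in BIN_LABELS if b in set(joined["bin"])] + [
        b for b in sorted(set(joined["bin"])) if b not in BIN_LABELS
    ]
    table = pd.crosstab(joined["bin"], joined["de_class"]).reindex(
        index=bin_order, columns=[c for c in DE_CLASSES if c in set(joined["de_class"])],
        fill_value=0,
    )
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping all-zero rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table degenerate after dropping zeros")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected_df = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return table, float(chi2), int(df), float(p), expected_df


def median_fold_change_by_bin(
    records: Sequence[GeneHmcRecord], expr: Sequence[ExpressionRecord]
) -> pd.Series:
    """Median log2 fold change per 5-hmC bin (lowest to highest density)."""
    joined = _join(records, expr)
    order = [b for b in BIN_LABELS if b in set(joined["bin"])] + [
        b for b in sorted(set(joined["bin"])) if b not in BIN_LABELS
    ]
    med = joined.groupby("bin")["log2fc"].median().reindex(order)
    med.name = "median_log2fc"
    return med
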