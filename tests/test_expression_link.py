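"""Expression classification and its association with 5-hmC density bins."""

import numpy as np
import pandas as pd
import pytest

from hmcdiff import (
    ExpressionRecord,
    GeneHmcRecord,
    SimulationConfig,
    bin_by_percentile,
    bin_class_association,
    classify_expression,
    expression_by_hmc_bin,
    make_expression,
    median_fold_change_by_bin,
)

from conftest import chi2_oracle


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "fpkm", "log2fc", "q_value"])


def expr_record(gid, fpkm=1.0, log2fc=0.0, q=1.0, cls="unchanged"):
    return ExpressionRecord(gid, fpkm, log2fc, q, cls)


class TestClassify:
    @pytest.mark.parametrize(
        "log2fc, q, expected",
        [
            (2.0, 0.01, "up"),
            (-2.0, 0.20, "unchanged"),  # fails q filter
            (0.0, 0.001, "unchanged"),  # fails effect-size filter
            (-1.5, 0.04, "down"),
            (1.0, 0.05, "up"),  # thresholds inclusive
        ],
    )
    def test_rule(self, log2fc, q, expected):
        (rec,) = classify_expression(de_table([("g", 1.0, log2fc, q)]))
        assert rec.de_class == expected

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify_expression(de_table([("g", 1, 0, 1), ("g", 2, 0, 1)]))


def _binned_records(densities):
    recs = [GeneHmcRecord(f"g{i:05d}", int(round(d * 1000)), 1000) for i, d in enumerate(densities)]
    return bin_by_percentile(recs)


class TestExpressionByBin:
    def test_monotone_link_gives_increasing_medians(self):
        cfg = SimulationConfig(seed=5, link_slope=1.0, link_noise_sd=0.3)
        rng = np.random.default_rng(5)
        densities = rng.lognormal(0, 1, 2_000)
        records = _binned_records(densities)
        table = make_expression(cfg, {r.gene_id: r.density for r in records})
        expr = classify_expression(table)
        summary = expression_by_hmc_bin(records, expr)
        medians = summary["median_fpkm"].to_numpy()
        assert np.all(np.diff(medians) > 0)

    def test_null_link_gives_similar_medians(self):
        cfg = SimulationConfig(seed=6, link_slope=0.0, link_noise_sd=0.3, induction_slope=0.0)
        rng = np.random.default_rng(6)
        densities = rng.lognormal(0, 1, 2_000)
        records = _binned_records(densities)
        table = make_expression(cfg, {r.gene_id: r.density for r in records})
        summary = expression_by_hmc_bin(records, classify_expression(table))
        medians = summary["median_fpkm"].to_numpy()
        assert medians.max() / medians.min() < 1.5

    def test_empty_join_rejected(self):
        records = _binned_records(np.arange(1, 11))
        with pytest.raises(ValueError, match="no genes shared"):
            expression_by_hmc_bin(records, [expr_record("absent")])

    def test_join_counts_missing_genes(self):
        records = _binned_records(np.arange(1, 11))
        expr = [expr_record(r.gene_id) for r in records[:6]] + [expr_record("xx")]
        summary = expression_by_hmc_bin(records, expr)
        assert summary["n"].sum() == 6
        assert summary.attrs["n_hmc_only"] == 4
        assert summary.attrs["n_expr_only"] == 1


class TestBinClassAssociation:
    def test_chi2_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(7)
        from scipy.stats import chi2_contingency

        for _ in range(100):
            table = rng.integers(1, 60, size=(int(rng.integers(2, 5)), int(rng.integers(2, 4))))
            chi2, _, _, _ = chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(chi2_oracle(table), rel=1e-9)

    def test_hand_computed_2x2(self):
        # planted so the joined table is [[30,70],[60,40]]
        records, expr = [], []
        i = 0
        for b_dens, (n_up, n_unch) in [(1, (30, 70)), (1000, (60, 40))]:
            for cls, count in [("up", n_up), ("unchanged", n_unch)]:
                for _ in range(count):
                    gid = f"g{i:05d}"
                    records.append(GeneHmcRecord(gid, b_dens * (1 + i % 3), 1000))
                    expr.append(expr_record(gid, log2fc=2.0 if cls == "up" else 0.0,
                                            q=0.01 if cls == "up" else 1.0, cls=cls))
                    i += 1
        binned = bin_by_percentile(records, cuts=(50,))
        table, chi2, df, p, expected = bin_class_association(binned, expr)
        assert df == 1
        assert chi2 == pytest.approx(18.1818, abs=0.01)
        assert p == pytest.approx(2.008e-5, rel=1e-3)

    def test_identical_rows_give_zero_statistic(self):
        records, expr = [], []
        for i in range(200):
            gid = f"g{i:05d}"
            records.append(GeneHmcRecord(gid, i + 1, 1000))
            cls = "up" if i % 4 == 0 else "unchanged"
            expr.append(expr_record(gid, log2fc=2.0 if cls == "up" else 0.0,
                                    q=0.01 if cls == "up" else 1.0, cls=cls))
        # classes assigned cyclically are independent of density rank
        records = bin_by_percentile(records, cuts=(50,))
        table, chi2, df, p, _ = bin_class_association(records, expr)
        assert chi2 < 8  # no association beyond sampling noise

    def test_margins_match_joined_counts(self):
        rng = np.random.default_rng(8)
        records = _binned_records(rng.lognormal(0, 1, 400))
        classes = rng.choice(["up", "down", "unchanged"], 400, p=[0.2, 0.2, 0.6])
        expr = [expr_record(r.gene_id,
                            log2fc={"up": 2.0, "down": -2.0, "unchanged": 0.0}[c],
                            q=0.01 if c != "unchanged" else 1.0, cls=c)
                for r, c in zip(records, classes)]
        table, *_ = bin_class_association(records, expr)
        assert table.to_numpy().sum() == 400

    def test_power_grows_with_sample_size(self):
        # top bin planted with twice the induced fraction
        rng = np.random.default_rng(9)
        pvals = []
        for n in (200, 2_000):
            records = _binned_records(rng.lognormal(0, 1, n))
            expr = []
            for r in records:
                p_up = 0.30 if r.bin == "P98_100" or r.bin == "P75_98" else 0.15
                cls = "up" if rng.random() < p_up else "unchanged"
                expr.append(expr_record(r.gene_id, log2fc=2.0 if cls == "up" else 0.0,
                                        q=0.01 if cls == "up" else 1.0, cls=cls))
            _, _, _, p, _ = bin_class_association(records, expr)
            pvals.append(p)
        assert pvals[1] < pvals[0]


class TestMedianFoldChange:
    def test_planted_top_bin_shift_recovered(self):
        rng = np.random.default_rng(10)
        records = _binned_records(rng.lognormal(0, 1, 1_000))
        expr = []
        for r in records:
            mu = 1.0 if r.bin == "P98_100" else 0.0
            expr.append(expr_record(r.gene_id, log2fc=float(rng.normal(mu, 0.2))))
        med = median_fold_change_by_bin(records, expr)
        assert med["P98_100"] == pytest.approx(1.0, abs=0.15)
        for b in ("P0_25", "P25_75", "P75_98"):
            assert med[b] == pytest.approx(0.0, abs=0.1)

    def test_all_zero_fold_changes(self):
        records = _binned_records(np.arange(1, 21))
        expr = [expr_record(r.gene_id, log2fc=0.0) for r in records]
        assert (median_fold_change_by_bin(records, expr) == 0).all()

    def test_single_gene_bin_median_is_its_value(self):
        records = _binned_records(np.arange(1, 5))  # 4 genes: top bin has 1
        expr = [expr_record(r.gene_id, log2fc=float(i)) for i, r in enumerate(records)]
        med = median_fold_change_by_bin(records, expr)
        top_gene = [r for r in records if r.bin == "P98_100"]
        assert len(top_gene) == 1
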