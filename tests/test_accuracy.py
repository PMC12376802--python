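import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from th2score import (
    ConfusionTable,
    chi_square_test,
    confusion_table,
    diagnostic_metrics,
    fisher_exact,
    metrics_from_rates,
)
from th2score.accuracy import clopper_pearson_interval, wilson_interval
from th2score.errors import DegenerateTableError

TABLE2 = ConfusionTable(tp=8, fp=1, fn=14, tn=25)


class TestConfusionTable:
    def test_from_crosstab_cohort(self, crosstab_cohort):
        from th2score import score_cohort

        frame = score_cohort(crosstab_cohort)
        pred = (frame["composite_score"] >= 3).to_numpy()
        truth = frame["asthma"].astype(bool).to_numpy()
        ct = confusion_table(pred, truth)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (8, 14, 1, 25)

    def test_perfect_predictions(self):
        truth = np.array([True, False, True])
        ct = confusion_table(truth, truth)
        assert ct.fp == 0 and ct.fn == 0

    def test_all_negative_predictions(self):
        ct = confusion_table([False] * 4, [True, False, True, False])
        assert ct.tp == 0 and ct.fp == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_table([True], [True, False])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=2)


class TestDiagnosticMetrics:
    def test_published_threshold3_panel(self):
        dm = diagnostic_metrics(TABLE2)
        assert dm.sensitivity.value == pytest.approx(8 / 22)
        assert dm.specificity.value == pytest.approx(25 / 26)
        assert dm.ppv.value == pytest.approx(8 / 9)
        assert dm.npv.value == pytest.approx(25 / 39)
        assert dm.lr_pos.value == pytest.approx(208 / 22)
        assert dm.sensitivity.render_pct() == "36.4%"
        assert dm.specificity.render_pct() == "96.2%"
        assert dm.ppv.render_pct() == "88.9%"
        assert dm.npv.render_pct() == "64.1%"
        assert dm.lr_pos.render() == "9.5"

    def test_perfect_classifier(self):
        dm = diagnostic_metrics(ConfusionTable(tp=10, fp=0, fn=0, tn=10))
        for m in (dm.sensitivity, dm.specificity, dm.ppv, dm.npv):
            assert m.value == 1.0
        assert dm.youden_j == pytest.approx(1.0)
        assert not dm.lr_pos.defined
        assert "specificity is 1" in dm.lr_pos.undefined_reason

    def test_hand_arithmetic_panel(self):
        dm = diagnostic_metrics(ConfusionTable(tp=3, fp=2, fn=1, tn=4))
        assert dm.sensitivity.value == pytest.approx(0.75)
        assert dm.specificity.value == pytest.approx(2 / 3)
        assert dm.ppv.value == pytest.approx(0.6)
        assert dm.npv.value == pytest.approx(0.8)
        assert dm.lr_pos.value == pytest.approx(2.25)

    def test_zero_denominator_flagged_not_fabricated(self):
        dm = diagnostic_metrics(ConfusionTable(tp=0, fp=0, fn=3, tn=5))
        assert not dm.ppv.defined
        assert dm.ppv.undefined_reason

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_bayes_consistency_and_lr_sign(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0 or tp + fp == 0 or fn + tn == 0:
            return
        dm = diagnostic_metrics(ConfusionTable(tp, fp, fn, tn))
        prev = (tp + fn) / (tp + fp + fn + tn)
        sens, spec = dm.sensitivity.value, dm.specificity.value
        expected_ppv = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert dm.ppv.value == pytest.approx(expected_ppv, abs=1e-12)
        if dm.lr_pos.defined and abs(dm.youden_j) > 1e-9:
            assert (dm.lr_pos.value > 1) == (dm.youden_j > 0)


class TestMetricsFromRates:
    def test_published_cutoff2_reconstruction(self):
        ct, dm = metrics_from_rates(0.545, 0.808, 22, 26)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (12, 10, 5, 21)
        assert dm.ppv.render_pct() == "70.6%"
        assert dm.npv.render_pct() == "67.7%"
        assert dm.lr_pos.render() == "2.8"

    def test_perfect_rates(self):
        _, dm = metrics_from_rates(1, 1, 5, 5)
        assert dm.ppv.value == 1 and dm.npv.value == 1

    def test_hand_case(self):
        ct, dm = metrics_from_rates(0.6, 0.7, 10, 10)
        assert ct.tp == 6 and ct.fp == 3
        assert dm.ppv.value == pytest.approx(6 / 9)

    def test_empty_positive_margin_flagged(self):
        _, dm = metrics_from_rates(0.0, 1.0, 4, 4)
        assert not dm.ppv.defined

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            metrics_from_rates(1.2, 0.5, 5, 5)
        with pytest.raises(ValueError):
            metrics_from_rates(0.5, 0.5, 0, 5)


class TestFisherExact:
    def test_published_crosstab(self):
        p = fisher_exact([[25, 14], [1, 8]])
        assert p < 0.01
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[25, 14], [1, 8]]).pvalue, abs=1e-12
        )

    def test_symmetric_table_p1(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_diagonal_3_by_hand(self):
        # support k=0..3; only k=0 and k=3 are as improbable as observed:
        # 2 * C(3,3)C(3,0)/C(6,3) = 2/20
        assert fisher_exact([[3, 0], [0, 3]]) == pytest.approx(0.1, abs=1e-12)

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_accepts_confusion_table(self):
        p_ct = fisher_exact(TABLE2)
        p_arr = fisher_exact(TABLE2.as_array())
        assert p_ct == p_arr

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_reference_for_n_le_60(self, a, b, c, d):
        n = a + b + c + d
        if n == 0 or n > 60:
            return
        if (a + b) in (0, n) or (a + c) in (0, n):
            return
        ours = fisher_exact([[a, b], [c, d]])
        ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(min(1.0, ref), abs=1e-10)


class TestChiSquare:
    def test_no_association(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res["statistic"] == 0 and res["p"] == 1 and res["df"] == 1

    def test_hand_computed_statistic(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res["statistic"] == pytest.approx(20 / 3, abs=1e-12)
        assert res["df"] == 1

    def test_prick_counts_significant(self):
        # prick positive/negative by group: 2/24 vs 12/10
        res = chi_square_test([[2, 24], [12, 10]])
        assert res["p"] < 0.01

    def test_matches_scipy_without_correction(self):
        table = [[7, 12, 3], [5, 9, 14]]
        res = chi_square_test(table)
        ref = scipy.stats.chi2_contingency(table, correction=False)
        assert res["statistic"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)
        assert res["df"] == ref.dof

    def test_yates_matches_scipy(self):
        table = [[8, 2], [1, 5]]
        res = chi_square_test(table, correction=True)
        ref = scipy.stats.chi2_contingency(table, correction=True)
        assert res["statistic"] == pytest.approx(ref.statistic)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test([[0, 0], [3, 4]])


class TestIntervals:
    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    @settings(max_examples=150, deadline=None)
    def test_contain_point_and_cp_never_narrower(self, k, n):
        if k > n:
            return
        w = wilson_interval(k, n)
        cp = clopper_pearson_interval(k, n)
        phat = k / n
        assert w[0] - 1e-12 <= phat <= w[1] + 1e-12
        assert cp[0] - 1e-12 <= phat <= cp[1] + 1e-12
        # width ordering holds away from the boundary; at k = 0 or k = n the
        # one-sided exact interval can be a hair narrower than Wilson
        if 0 < k < n:
            assert (cp[1] - cp[0]) >= (w[1] - w[0]) - 1e-9

    def test_clopper_pearson_matches_beta_quantiles(self):
        lo, hi = clopper_pearson_interval(3, 10)
        assert lo == pytest.approx(scipy.stats.beta.ppf(0.025, 3, 8))
        assert hi == pytest.approx(scipy.stats.beta.ppf(0.975, 4, 7))

    def test_ci_method_switch(self):
        dm_w = diagnostic_metrics(TABLE2, ci_method="wilson")
        dm_cp = diagnostic_metrics(TABLE2, ci_method="clopper_pearson")
        assert dm_w.sensitivity.ci != dm_cp.sensitivity.ci
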