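import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from th2score import auc, empirical_roc, score_cohort, youden_optimal


def brute_force_curve(values, labels):
    """Independent per-threshold sweep: positive iff value >= t."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    points = {}
    for t in np.concatenate(([np.inf], np.unique(v))):
        pred = v >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        points[float(t)] = (sens, spec)
    return points


class TestEmpiricalRoc:
    def test_perfectly_separated(self):
        curve = empirical_roc([1, 2, 3, 4], [False, False, True, True])
        sens, spec = curve.operating_point(3)
        assert sens == 1.0 and spec == 1.0

    def test_crosstab_operating_point(self, crosstab_cohort):
        frame = score_cohort(crosstab_cohort)
        curve = empirical_roc(
            frame["composite_score"].to_numpy(float),
            frame["asthma"].astype(bool).to_numpy(),
        )
        sens, spec = curve.operating_point(3)
        assert sens == pytest.approx(8 / 22)   # 36.4%
        assert spec == pytest.approx(25 / 26)  # 96.2%

    def test_tied_values_collapse_to_single_point(self, rng):
        v = rng.integers(0, 5, 60).astype(float)
        y = rng.random(60) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        curve = empirical_roc(v, y)
        assert len(curve.thresholds) == len(np.unique(v)) + 1
        ref = brute_force_curve(v, y)
        for t, sn, sp in zip(curve.thresholds, curve.sens, curve.spec):
            rs, rp = ref[float(t)]
            assert sn == pytest.approx(rs) and sp == pytest.approx(rp)

    def test_endpoints_present(self):
        curve = empirical_roc([1, 2, 3], [True, False, True])
        assert curve.sens[0] == 0 and curve.spec[0] == 1     # +inf sentinel
        assert curve.sens[-1] == 1 and curve.spec[-1] == 0   # min threshold

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2], [True, True])

    def test_lower_positive_orientation(self):
        hi = empirical_roc([1, 2, 3, 4], [True, True, False, False],
                           orientation="lower_positive")
        sens, spec = hi.operating_point(2)
        assert sens == 1.0 and spec == 1.0


class TestAuc:
    def test_pair_counting_with_tie(self):
        # pairs (1,2),(1,3),(2,2),(2,3) -> 1 + 1 + 0.5 + 1 = 3.5 of 4
        res = auc([1, 2, 2, 3], [False, False, True, True])
        assert res.auc == pytest.approx(0.875)

    def test_identical_distributions(self):
        res = auc([1, 2, 3, 1, 2, 3], [False] * 3 + [True] * 3)
        assert res.auc == pytest.approx(0.5)

    def test_binary_marker_identity(self):
        # AUC of a 0/1 marker equals (sens + spec)/2 of that marker
        y = np.array([True] * 10 + [False] * 14)
        marker = np.array([1] * 7 + [0] * 3 + [1] * 4 + [0] * 10, dtype=float)
        sens, spec = 7 / 10, 10 / 14
        res = auc(marker, y)
        assert res.auc == pytest.approx((sens + spec) / 2)

    def test_ci_contains_point_and_p_sane(self, rng):
        v = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        y = np.repeat([False, True], 40)
        res = auc(v, y)
        assert res.ci[0] <= res.auc <= res.ci[1]
        assert 0 <= res.p_value <= 1

    def test_bootstrap_ci(self, rng):
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        y = np.repeat([False, True], 30)
        res = auc(v, y, ci_method="bootstrap", n_boot=300, rng=rng)
        assert res.ci[0] <= res.auc <= res.ci[1]

    @given(
        n_neg=st.integers(2, 15), n_pos=st.integers(2, 15),
        seed=st.integers(0, 10_000), tied=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_trapezoid_equals_mann_whitney_everywhere(
        self, n_neg, n_pos, seed, tied
    ):
        # auc() raises internally if the two routes disagree; also check
        # against direct O(n^2) pair counting
        r = np.random.default_rng(seed)
        if tied:
            v = r.integers(0, 4, n_neg + n_pos).astype(float)
        else:
            v = r.normal(size=n_neg + n_pos)
        y = np.repeat([False, True], [n_neg, n_pos])
        res = auc(v, y)
        pos, neg = v[y], v[~y]
        pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        assert res.auc == pytest.approx(pairs / (n_pos * n_neg), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_orientation_complement(self, seed):
        r = np.random.default_rng(seed)
        v = r.integers(0, 6, 30).astype(float)
        y = np.repeat([False, True], [14, 16])
        a1 = auc(v, y).auc
        a2 = auc(-v, y).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        v = rng.integers(0, 8, 100).astype(float)
        y = rng.random(100) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert auc(v, y).auc == pytest.approx(roc_auc_score(y, v), abs=1e-12)


class TestYouden:
    def test_exhaustive_sweep_example(self):
        v = np.array([10, 11, 12, 25, 20, 26, 27, 28, 29], dtype=float)
        y = np.array([False] * 4 + [True] * 5)
        opt = youden_optimal(empirical_roc(v, y))
        assert opt["cutoff"] == 26
        assert opt["j"] == pytest.approx(0.8)
        assert opt["sens"] == pytest.approx(0.8)
        assert opt["spec"] == pytest.approx(1.0)

    def test_perfect_separation(self):
        v = np.array([1, 2, 10, 11], dtype=float)
        y = np.array([False, False, True, True])
        opt = youden_optimal(empirical_roc(v, y))
        assert opt["j"] == pytest.approx(1.0)
        assert opt["cutoff"] == 10  # lowest threshold achieving J = 1

    def test_all_values_identical(self):
        v = np.ones(6)
        y = np.array([False, True] * 3)
        opt = youden_optimal(empirical_roc(v, y))
        assert opt["j"] == pytest.approx(0.0)

    def test_tie_break_prefers_higher_specificity(self):
        # sens/spec tradeoffs with equal J at two thresholds
        v = np.array([1, 2, 3, 4], dtype=float)
        y = np.array([False, True, False, True])
        opt = youden_optimal(empirical_roc(v, y))
        roc = empirical_roc(v, y)
        j = roc.sens + roc.spec - 1
        ties = np.isclose(j, j.max())
        assert opt["spec"] == max(roc.spec[ties])

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=60, deadline=None)
    def test_j_matches_exhaustive_metric_sweep(self, seed):
        # cross-module consistency with the confusion-table youden_j
        from th2score import confusion_table, diagnostic_metrics

        r = np.random.default_rng(seed)
        v = r.integers(0, 6, 25).astype(float)
        y = r.random(25) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        roc = empirical_roc(v, y)
        best = youden_optimal(roc)["j"]
        sweep = max(
            diagnostic_metrics(confusion_table(v >= t, y)).youden_j
            for t in np.unique(v)
        )
        assert best == pytest.approx(max(sweep, 0.0), abs=1e-12)
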