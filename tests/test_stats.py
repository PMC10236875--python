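"""Diagnostic, ROC, regression and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from tavrsim import stats as st
from tavrsim.errors import DegenerateInputError, InvalidParameterError


class TestTwoByTwo:
    def test_reconstructed_cpi_table_metrics(self):
        # sensitivity 70%, specificity 66% on 80 patients with 27 events
        t = st.reconstruct_from_operating_point(80, 27, 0.70, 0.66)
        assert (t.tp, t.fp, t.fn, t.tn) == (19, 18, 8, 35)
        d = st.two_by_two_metrics(t)
        assert round(d.odds_ratio, 2) == 4.62
        assert d.accuracy == pytest.approx(0.675)
        assert d.ppv == pytest.approx(0.514, abs=0.001)
        assert d.npv == pytest.approx(0.81, abs=0.005)
        assert d.or_ci[0] == pytest.approx(1.69, abs=0.02)
        assert d.or_ci[1] == pytest.approx(12.60, abs=0.05)

    def test_reconstructed_cpmax_table_from_incidences(self):
        t = st.reconstruct_from_stratum_incidence(80, 27, 0.537, 0.128)
        assert (t.tp, t.fp, t.fn, t.tn) == (22, 19, 5, 34)
        assert round(st.two_by_two_metrics(t).odds_ratio, 2) == 7.87

    def test_symmetric_table(self):
        d = st.two_by_two_metrics(st.TwoByTwo(10, 10, 10, 10))
        assert d.odds_ratio == pytest.approx(1.0)
        assert d.accuracy == pytest.approx(0.5)
        assert d.fisher_p == pytest.approx(1.0)

    def test_zero_cell_haldane_correction_flagged(self):
        d = st.two_by_two_metrics(st.TwoByTwo(5, 0, 3, 7))
        assert d.continuity_corrected
        assert np.isfinite(d.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.TwoByTwo(-1, 0, 0, 2)


class TestRoc:
    def test_perfect_separation(self):
        roc = st.roc_auc([0, 0, 1, 2, 2, 3], [False, False, False, True, True, True])
        assert roc.auc == 1.0

    def test_null_association_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.4
        roc = st.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.03)
        assert roc.ci_low <= roc.auc <= roc.ci_high
        assert roc.p_value > 0.001

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.roc_auc([1.0, 2.0], [True, True])

    def test_empirical_converges_to_binormal(self):
        target = st.binormal_auc(28.3, 15.8, 15.6, 11.2)
        emp = st.simulate_group_auc(28.3, 15.8, 15.6, 11.2, n_per_group=60_000, seed=1)
        assert emp == pytest.approx(target, abs=0.005)

    def test_delong_ci_width_shrinks_with_n(self):
        w = []
        for n in (200, 5000):
            roc_n = st.roc_auc(
                *_group_draws(n, seed=3)
            )
            w.append(roc_n.ci_high - roc_n.ci_low)
        assert w[1] < w[0]


def _group_draws(n, seed):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
    scores = np.concatenate([rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)])
    return scores, labels


class TestBinormal:
    def test_printed_group_parameters(self):
        assert st.binormal_auc(28.3, 15.8, 15.6, 11.2) == pytest.approx(0.744, abs=0.001)
        assert st.binormal_auc(0.51, 0.20, 0.36, 0.24) == pytest.approx(0.684, abs=0.001)

    def test_equal_means_half(self):
        assert st.binormal_auc(1.0, 2.0, 1.0, 3.0) == 0.5

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.binormal_auc(1.0, 0.0, 1.0, 0.0)


class TestOptimalCutoff:
    def test_perfect_separation_j_one(self):
        roc = st.roc_auc([0.0, 0.1, 0.9, 1.0], [False, False, True, True])
        cut = st.optimal_cutoff(roc)
        assert cut.youden_j == pytest.approx(1.0)
        assert 0.1 < cut.threshold <= 0.9

    def test_reconstructed_operating_point_j(self):
        # binary flag scores replicating the (19, 18, 8, 35) table
        scores = np.array([1.0] * 37 + [0.0] * 43)
        labels = np.array([True] * 19 + [False] * 18 + [True] * 8 + [False] * 35)
        cut = st.optimal_cutoff(st.roc_auc(scores, labels))
        assert cut.youden_j == pytest.approx(19 / 27 + 35 / 53 - 1.0, abs=1e-9)
        assert cut.youden_j == pytest.approx(0.364, abs=0.001)


class TestLogistic:
    def test_univariate_binary_flag_equals_two_by_two_or(self):
        y = np.array([1] * 19 + [0] * 18 + [1] * 8 + [0] * 35)
        x = pd.DataFrame({"flag": [1.0] * 37 + [0.0] * 43})
        fit = st.logistic_fit(y, x)
        assert fit.odds_ratio("flag") == pytest.approx(4.62, abs=0.005)

    @settings(max_examples=15, deadline=None)
    @given(
        tp=st_h.integers(2, 30), fp=st_h.integers(2, 30),
        fn=st_h.integers(2, 30), tn=st_h.integers(2, 30),
    )
    def test_or_equivalence_property(self, tp, fp, fn, tn):
        t = st.TwoByTwo(tp, fp, fn, tn)
        d = st.two_by_two_metrics(t)
        y = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
        x = pd.DataFrame({"flag": [1.0] * (tp + fp) + [0.0] * (fn + tn)})
        fit = st.logistic_fit(y, x)
        assert fit.odds_ratio("flag") == pytest.approx(d.odds_ratio, rel=1e-3)

    def test_independent_predictor_or_near_one(self):
        rng = np.random.default_rng(2)
        y = rng.random(5000) < 0.3
        x = pd.DataFrame({"noise": rng.normal(size=5000)})
        fit = st.logistic_fit(y, x)
        assert fit.odds_ratio("noise") == pytest.approx(1.0, abs=0.1)

    def test_three_predictor_fit_reports_three_ors(self):
        rng = np.random.default_rng(3)
        n = 500
        x = pd.DataFrame(
            {
                "cpi_flag": rng.random(n) < 0.45,
                "cpmax_flag": rng.random(n) < 0.5,
                "depth_flag": rng.random(n) < 0.8,
            }
        ).astype(float)
        eta = -1.5 + 0.5 * x["cpi_flag"] + 1.5 * x["cpmax_flag"] + 0.8 * x["depth_flag"]
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        fit = st.logistic_fit(y, x)
        assert set(fit.table.index) == {"cpi_flag", "cpmax_flag", "depth_flag"}
        assert np.isfinite(fit.table["or"]).all()

    def test_complete_separation_flagged(self):
        y = np.array([0] * 20 + [1] * 20)
        x = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        fit = st.logistic_fit(y, x)
        assert fit.separation

    def test_single_class_outcome_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.logistic_fit(np.zeros(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestSurvival:
    def test_exponential_rate_ratio_recovered(self):
        rng = np.random.default_rng(5)
        n = 5000
        g = np.r_[np.zeros(n, int), np.ones(n, int)]
        rate = np.where(g == 1, 0.3, 0.1)
        t = rng.exponential(1.0 / rate)
        event = t <= 5.0
        t = np.minimum(t, 5.0)
        res = st.survival_analysis(t, event, g)
        assert 2.7 <= res.hazard_ratio <= 3.3
        assert res.hr_ci[0] < res.hazard_ratio < res.hr_ci[1]
        assert res.logrank_p < 1e-6

    def test_null_groups(self):
        rng = np.random.default_rng(6)
        n = 3000
        t = rng.exponential(5.0, 2 * n)
        event = t <= 3.0
        t = np.minimum(t, 3.0)
        g = np.r_[np.zeros(n, int), np.ones(n, int)]
        res = st.survival_analysis(t, event, g)
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.15)

    def test_summary_format(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(2.0, 200)
        res = st.survival_analysis(
            np.minimum(t, 3.0), t <= 3.0, np.arange(200) % 2
        )
        s = res.summary()
        assert "hazard ratio" in s and "95% CI" in s and "log-rank" in s

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            st.survival_analysis([1.0, 2.0], [False, False], [0, 1])


class TestGroupTests:
    def test_identical_groups_null(self):
        a = np.arange(10.0)
        tstat, p = st.t_test(a, a)
        assert tstat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_power_under_printed_effect_size(self):
        rng = np.random.default_rng(8)
        rejections = 0
        trials = 60
        for _ in range(trials):
            g1 = rng.normal(28.3, 15.8, 27)
            g0 = rng.normal(15.6, 11.2, 53)
            _, p = st.t_test(g1, g0)
            rejections += p < 0.05
        assert rejections / trials > 0.5

    def test_anova_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            groups = [rng.normal(0.0, 1.0, 20) for _ in range(4)]
            _, p = st.anova(*groups)
            ps.append(p)
        assert 0.01 < np.mean(np.asarray(ps) < 0.05) < 0.12

    def test_explicit_dispatch(self):
        a, b = np.arange(10.0), np.arange(10.0) + 0.5
        assert st.compare_groups(a, b, test="mannwhitney")[1] > 0.0
        with pytest.raises(InvalidParameterError):
            st.compare_groups(a, b, test="anova2")

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.4
        perm = rng.permutation(500)
        assert st.roc_auc(scores, labels).auc == pytest.approx(
            st.roc_auc(scores[perm], labels[perm]).auc, abs=1e-12
        )


def test_pooled_mean_matches_prevalence_weighting():
    assert st.pooled_mean([28.3, 15.6], [27, 53]) == pytest.approx(19.886, abs=0.001)
    assert st.pooled_mean([0.51, 0.36], [27, 53]) == pytest.approx(0.4106, abs=0.0005)


def test_results_ledger_columns():
    df = st.results_ledger([{"analysis": "a", "estimate": 1.0}])
    assert list(df.columns) == ["analysis", "estimate", "ci_low", "ci_high", "p"]
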