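import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test

from mc5 import (
    dichotomize,
    kaplan_meier,
    logrank_test,
    multivariable_cox,
    optimal_cutpoint,
    univariate_cox,
)
from mc5.survstats import logrank_z, relabel_by_prognosis


def _tie_free(rng, n, beta=0.0, censor=0.3):
    """Continuous covariate, exponential times, tie-free with probability 1."""
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.uniform(0, np.quantile(t, 1 - censor) * 2, n) if censor > 0 else np.full(n, np.inf)
    e = (t <= c).astype(float)
    return x, np.minimum(t, c), e


class TestKaplanMeier:
    def test_textbook_hand_example(self):
        # classic 6-subject example: events at 1, 3, 5; censored at 2, 4, 6
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        km = kaplan_meier(t, e)
        assert np.allclose(km.times, [1.0, 3.0, 5.0])
        assert np.allclose(km.survival, [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2])

    def test_matches_lifelines_with_ties(self, rng):
        t = rng.integers(1, 15, 80).astype(float)
        e = rng.integers(0, 2, 80).astype(float)
        e[0] = 1.0
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et in km.times:
            assert km.survival_at(et) == pytest.approx(
                float(kmf.survival_function_at_times(et).iloc[0]), abs=1e-10
            )

    def test_survival_at_before_first_event_is_one(self):
        km = kaplan_meier(np.array([2.0, 3.0]), np.array([1.0, 1.0]))
        assert km.survival_at(1.0) == 1.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestLogrank:
    def test_two_group_matches_lifelines(self, rng):
        x, t, e = _tie_free(rng, 120, beta=0.8)
        g = np.where(x > 0, "a", "b")
        chi2, p = logrank_test(g, t, e)
        res = ll_logrank(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-8)
        assert p == pytest.approx(res.p_value, rel=1e-8)

    def test_three_group_matches_lifelines(self, rng):
        t = rng.exponential(1.0, 150)
        e = np.ones(150)
        g = np.repeat(["a", "b", "c"], 50)
        t[g == "c"] *= 0.5
        chi2, p = logrank_test(g, t, e)
        res = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-8)
        assert p == pytest.approx(res.p_value, rel=1e-8)

    def test_identical_groups_null(self, rng):
        t = np.tile(rng.exponential(1.0, 30), 2)
        e = np.ones(60)
        g = np.repeat(["a", "b"], 30)
        chi2, _ = logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_z_squares_to_chi2(self, rng):
        x, t, e = _tie_free(rng, 80, beta=0.5)
        g = np.where(x > 0, "a", "b")
        z = logrank_z(g, t, e)
        chi2, _ = logrank_test(g, t, e)
        assert z**2 == pytest.approx(chi2, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test(np.array(["a", "a"]), np.array([1.0, 2.0]), np.array([1.0, 1.0]))


class TestCox:
    def test_univariate_matches_lifelines_tie_free(self, rng):
        x, t, e = _tie_free(rng, 200, beta=0.7)
        fit = univariate_cox(x, t, e)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e", fit_options={"precision": 1e-10})
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)
        assert fit.p == pytest.approx(cph.summary.loc["x", "p"], rel=1e-4)

    def test_breslow_ties_match_statsmodels(self, rng):
        # lifelines uses Efron ties; statsmodels PHReg provides a Breslow oracle
        from statsmodels.duration.hazard_regression import PHReg

        x = rng.normal(size=100)
        t = rng.integers(1, 8, 100).astype(float)  # heavy ties
        e = rng.integers(0, 2, 100).astype(float)
        e[:10] = 1.0
        fit = univariate_cox(x, t, e)
        res = PHReg(t, x[:, None], status=e, ties="breslow").fit()
        assert fit.beta == pytest.approx(res.params[0], abs=1e-6)
        assert fit.se == pytest.approx(res.bse[0], abs=1e-6)

    def test_multivariable_matches_lifelines(self, rng):
        n = 250
        x1, t, e = _tie_free(rng, n, beta=0.6)
        x2 = rng.normal(size=n)
        age = rng.uniform(40, 80, n)
        cov = pd.DataFrame({"x1": x1, "x2": x2, "age": age})
        fits = {f.name: f for f in multivariable_cox(cov, t, e)}
        df = cov.assign(t=t, e=e)
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e", fit_options={"precision": 1e-10})
        for name in ("x1", "x2", "age"):
            assert fits[name].beta == pytest.approx(cph.params_[name], abs=1e-6)
            assert fits[name].se == pytest.approx(cph.standard_errors_[name], abs=1e-6)

    def test_categorical_one_hot_first_level_dropped(self, rng):
        n = 150
        x, t, e = _tie_free(rng, n, beta=0.5)
        stage = rng.choice(["I", "II", "III"], n)
        cov = pd.DataFrame({"x": x, "stage": pd.Categorical(stage)})
        fits = multivariable_cox(cov, t, e)
        names = {f.name for f in fits}
        assert names == {"x", "stage_II", "stage_III"}

    def test_collinear_design_rejected(self, rng):
        n = 100
        x, t, e = _tie_free(rng, n, beta=0.3)
        cov = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.raises(ValueError, match="collinear"):
            multivariable_cox(cov, t, e)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfect separation: all events in the high-covariate group
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        fit = univariate_cox(x, t, e)
        assert not fit.converged
        assert np.isinf(fit.beta)

    def test_hr_ci_consistency(self, rng):
        x, t, e = _tie_free(rng, 150, beta=0.5)
        fit = univariate_cox(x, t, e)
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        assert fit.ci_low < fit.hr < fit.ci_high

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            univariate_cox(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestCutpoint:
    def test_matches_exhaustive_search(self, rng):
        n = 80
        s = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * s))
        e = np.ones(n)
        res = optimal_cutpoint(s, t, e, minprop=0.1)
        # brute force over every admissible midpoint
        uniq = np.unique(s)
        best_abs, best_cut = -1.0, None
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            high = s > cut
            if min(high.sum(), (~high).sum()) < 0.1 * n:
                continue
            z = abs(logrank_z(np.where(high, "h", "l"), t, e))
            if z > best_abs + 1e-12:
                best_abs, best_cut = z, cut
        assert res.cutoff == pytest.approx(best_cut)
        assert abs(res.statistic) == pytest.approx(best_abs)

    def test_minprop_respected(self, rng):
        s = np.arange(20, dtype=float)
        t = rng.exponential(1, 20)
        e = np.ones(20)
        res = optimal_cutpoint(s, t, e, minprop=0.25)
        assert min(res.n_high, res.n_low) >= 5

    def test_separated_groups_found(self, rng):
        n = 100
        s = np.concatenate([rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)])
        t = np.concatenate([rng.exponential(0.3, n // 2), rng.exponential(3.0, n // 2)])
        e = np.ones(n)
        res = optimal_cutpoint(s, t, e)
        assert -1.0 < res.cutoff < 1.0

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            optimal_cutpoint(np.ones(10), np.arange(1.0, 11.0), np.ones(10))


class TestRelabelAndDichotomize:
    def test_relabel_anchors_better_prognosis_to_one(self, rng):
        n = 200
        lab = pd.Series(np.repeat([1, 2], n // 2), index=[f"s{j}" for j in range(n)])
        t = np.where(lab == 1, rng.exponential(0.3, n), rng.exponential(3.0, n))
        e = np.ones(n)
        out = relabel_by_prognosis(lab, t, e)
        # original cluster 2 lives longer, so it becomes cluster 1
        assert (out[lab == 2] == 1).all() and (out[lab == 1] == 2).all()
        # idempotent on already-anchored labels
        again = relabel_by_prognosis(out, t, e)
        assert (again == out).all()

    def test_dichotomize_strict_threshold(self):
        labels = dichotomize(np.array([0.9, 1.0, 1.1]), 1.0)
        assert list(labels) == ["low", "low", "high"]
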