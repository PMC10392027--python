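"""Cox partial likelihood, Newton fitting, Breslow baseline, KM, log-rank —
each checked against brute-force enumeration and independent library oracles.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepcox import (
    breslow_cumhaz,
    cox_partial_loglik,
    fit_cox,
    km_curve,
    logrank_test,
)
from tests.conftest import make_ph_data


def brute_force_loglik(eta, time, event):
    """Direct risk-set enumeration with Breslow tie handling."""
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    total = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = (time == t) & (event == 1)
        total += eta[d].sum() - d.sum() * np.log(np.exp(eta[at_risk]).sum())
    return total


def grid_search_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Maximize the single-covariate partial likelihood over a dense grid."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_partial_loglik(x * b, time, event) for b in grid]
    return grid[int(np.argmax(lls))]


class TestPartialLoglik:
    def test_single_event_is_zero(self):
        assert cox_partial_loglik([3.7], [5.0], [1]) == pytest.approx(0.0)

    def test_two_subjects_risk_set(self):
        val = cox_partial_loglik([0.0, 0.0], [1.0, 2.0], [1, 0])
        assert val == pytest.approx(-np.log(2.0))

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(2, 11)
            time = rng.uniform(1, 10, n)
            if rng.uniform() < 0.3:  # force ties sometimes
                time = np.round(time)
                time = np.maximum(time, 1.0)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            eta = rng.normal(size=n)
            assert cox_partial_loglik(eta, time, event) == pytest.approx(
                brute_force_loglik(eta, time, event), abs=1e-10
            )

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            cox_partial_loglik([0.0, 1.0], [1.0, 2.0], [0, 0])

    @given(shift=st.floats(-50, 50), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        n = 8
        time = rng.uniform(1, 10, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        eta = rng.normal(size=n)
        a = cox_partial_loglik(eta, time, event)
        b = cox_partial_loglik(eta + shift, time, event)
        assert abs(a - b) < 1e-9


class TestFitCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 0, 0])

    def test_binary_covariate_matches_grid_search(self):
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 1])
        fit = fit_cox(x, time, event)
        assert fit.beta[0] == pytest.approx(
            grid_search_beta(x, time, event), abs=1e-3
        )

    def test_grid_search_random_instances(self):
        rng = np.random.default_rng(1)
        for i in range(8):
            n = int(rng.integers(6, 15))
            x = rng.integers(0, 2, n).astype(float)
            if x.std() == 0:
                x[0] = 1 - x[0]
            time = rng.uniform(1, 20, n)
            event = rng.integers(0, 2, n)
            if event.sum() < 2:
                event[:2] = 1
            fit = fit_cox(x, time, event)
            if abs(fit.beta[0]) < 4.5:  # inside the oracle's grid
                assert fit.beta[0] == pytest.approx(
                    grid_search_beta(x, time, event), abs=1e-3
                )

    def test_recovers_true_beta(self):
        X, time, event = make_ph_data(2000, [0.7], seed=2)
        fit = fit_cox(X, time, event)
        assert fit.beta[0] == pytest.approx(0.7, abs=0.1)

    def test_matches_lifelines_no_ties(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        X, time, event = make_ph_data(300, [0.5, -0.3, 0.2], seed=3)
        fit = fit_cox(X, time, event)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_hr_and_ci_consistent(self):
        X, time, event = make_ph_data(200, [0.4], seed=4)
        fit = fit_cox(X, time, event)
        lo, hi = fit.ci
        assert np.all(lo < fit.hr) and np.all(fit.hr < hi)
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(40)
        n = 120
        X = rng.normal(size=(n, 2))
        time = np.ceil(rng.exponential(10, n))  # heavy ties
        event = (rng.uniform(size=n) < 0.7).astype(int)
        fit = fit_cox(X, time, event, ties="efron")
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_monotone_likelihood_warns(self):
        # perfectly separated risk ordering
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.ones(6, dtype=int)
        with pytest.warns(RuntimeWarning):
            fit = fit_cox(x, time, event)
        assert not fit.converged


class TestKaplanMeier:
    def test_no_censoring_product(self):
        km = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert km.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert len(km.times) == 0
        assert km.at([0.5, 2.5]) == pytest.approx([1.0, 1.0])

    def test_censoring_shrinks_risk_set(self):
        km = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.at(1.0)[0] == pytest.approx(2.0 / 3.0)
        assert km.at(3.0)[0] == pytest.approx(0.0)  # risk set of 1 at t=3

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(5)
        time = rng.uniform(1, 50, 200)
        km = km_curve(time, np.ones(200, dtype=int))
        ecdf = np.array([(time <= t).mean() for t in km.times])
        assert np.allclose(km.survival, 1 - ecdf, atol=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(6)
        time = rng.uniform(1, 40, 150)
        event = rng.integers(0, 2, 150)
        km = km_curve(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        ours = km.at(km.times)
        theirs = kmf.predict(km.times).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_example(self):
        # groups A: events at 1, 3; B: event at 2, censored 4
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
        # tabulate each event time's 2x2 by hand:
        # t=1: nA=3 nB=3 d=1 dA=1 -> e=0.5 v=0.25
        # t=2: nA=2 nB=3 d=1 dA=0 -> e=0.4 v=0.24
        # t=3: nA=2 nB=2 d=1 dA=1 -> e=0.5 v=0.25
        # t=6: nA=0 nB=1 d=1 dA=0 -> e=0.0 v=0.0
        o_minus_e = (1 - 0.5) + (0 - 0.4) + (1 - 0.5) + 0.0
        var = 0.25 + 0.24 + 0.25
        chi2, _ = logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        ta, tb = rng.uniform(1, 30, 60), rng.uniform(1, 20, 50)
        ea, eb = rng.integers(0, 2, 60), rng.integers(0, 2, 50)
        chi2, p = logrank_test(ta, ea, tb, eb)
        res = ll_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
        assert p == pytest.approx(res.p_value, abs=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestBreslowBaseline:
    def test_baseline_survival_matches_km_at_zero_covariates(self):
        rng = np.random.default_rng(8)
        n = 500
        time = rng.weibull(1.2, n) * 30
        time = np.maximum(time, 1e-6)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        bt, bh = breslow_cumhaz(np.zeros(n), time, event)
        km = km_curve(time, event)
        s0 = np.exp(-bh)
        assert np.max(np.abs(s0 - km.at(bt))) < 0.02

    def test_cumhaz_nondecreasing_and_fit_consistency(self):
        X, time, event = make_ph_data(200, [0.5, -0.2], seed=9)
        fit = fit_cox(X, time, event)
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)
        surv = fit.predict_survival(X[:5], [6.0, 12.0, 24.0])
        assert np.all((surv >= 0) & (surv <= 1))
        assert np.all(np.diff(surv, axis=1) <= 1e-12)
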