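"""Univariate screen calibration, L1 path correctness against independent
solvers, and signature assembly behavior.
"""

import numpy as np
import pytest

from tepcox import (
    SimulationConfig,
    build_signature,
    fit_cox,
    fit_preprocess,
    generate_cohort,
    lambda_max,
    lambda_path,
    lambda_path_cv,
    lasso_cox,
    univariate_screen,
)
from tepcox.survival import cox_loglik_grad_eta, cox_partial_loglik
from tests.conftest import expr_from_array, make_ph_data


def ista_lasso_cox(X, time, event, lam, n_iter=20_000, tol=1e-12):
    """Independent proximal-gradient (ISTA) solver for the same objective."""
    n, p = X.shape
    beta = np.zeros(p)
    # Lipschitz bound for the mean negative partial loglik gradient
    L = np.linalg.norm(X, 2) ** 2 / n
    step = 1.0 / L
    soft = lambda v, s: np.sign(v) * np.maximum(np.abs(v) - s, 0.0)
    prev_obj = np.inf
    for _ in range(n_iter):
        _, g_eta, _ = cox_loglik_grad_eta(X @ beta, time, event)
        grad = -(X.T @ g_eta) / n
        beta_new = soft(beta - step * grad, step * lam)
        obj = -cox_partial_loglik(X @ beta_new, time, event) / n \
            + lam * np.abs(beta_new).sum()
        if abs(prev_obj - obj) < tol and np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta, prev_obj = beta_new, obj
    return beta


class TestUnivariateScreen:
    def test_betas_match_fit_cox_gene_by_gene(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        screen = univariate_screen(z, clinical)
        cl = clinical.aligned_to(z.sample_ids)
        rng = np.random.default_rng(0)
        for gi in rng.choice(z.n_genes, size=12, replace=False):
            fit = fit_cox(z.values[gi], cl.time, cl.event)
            row = screen.table.iloc[gi]
            assert abs(fit.beta[0] - row["beta"]) < 1e-10
            assert abs(fit.se[0] - row["se"]) < 1e-10

    def test_constant_gene_never_passes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        X[:, 2] = 1.0
        _, time, event = make_ph_data(100, [0.0], seed=2)
        expr = expr_from_array(X)
        with pytest.warns(RuntimeWarning, match="constant"):
            screen = univariate_screen(expr, _clinical_from(time, event))
        assert not screen.table.loc[2, "passed"]
        assert np.isnan(screen.table.loc[2, "beta"])

    def test_null_type_one_error_calibrated(self):
        """On pure-noise genes the passing fraction tracks alpha."""
        rng = np.random.default_rng(3)
        n, g = 300, 2000
        X = rng.normal(size=(n, g))
        _, time, event = make_ph_data(n, [0.0], seed=4)
        screen = univariate_screen(expr_from_array(X), _clinical_from(time, event))
        assert screen.table["passed"].mean() == pytest.approx(0.05, abs=0.01)

    def test_signal_power(self):
        """Genes with |beta| = 0.5 at n = 500 essentially always pass."""
        hits = trials = 0
        for seed in range(10):
            X, time, event = make_ph_data(
                500, [0.5] * 5 + [0.0] * 5, seed=100 + seed
            )
            screen = univariate_screen(
                expr_from_array(X), _clinical_from(time, event)
            )
            hits += screen.table["passed"][:5].sum()
            trials += 5
        assert hits / trials > 0.95

    def test_order_invariance(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        rng = np.random.default_rng(5)
        perm = rng.permutation(z.n_genes)
        z_perm = z.subset_genes([z.gene_ids[i] for i in perm])
        a = univariate_screen(z, clinical).table.set_index("gene_id")
        b = univariate_screen(z_perm, clinical).table.set_index("gene_id")
        assert np.allclose(
            a.loc[b.index, "beta"].to_numpy(), b["beta"].to_numpy(), atol=1e-12
        )


def _clinical_from(time, event):
    import pandas as pd

    from tepcox import ClinicalTable

    n = len(time)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "time_months": time,
                "event": event,
            }
        )
    )


class TestLassoCox:
    @pytest.fixture(scope="class")
    def problem(self):
        X, time, event = make_ph_data(
            200, [0.6, -0.4, 0.3, 0.0, 0.0], seed=6
        )
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        return X, time, event

    def test_empty_active_set_at_lambda_max(self, problem):
        X, time, event = problem
        lmax = lambda_max(X, time, event)
        assert np.all(lasso_cox(X, time, event, lmax) == 0)
        assert np.all(lasso_cox(X, time, event, lmax * 2) == 0)
        assert np.any(lasso_cox(X, time, event, lmax * 0.95) != 0)

    def test_lambda_zero_equals_newton(self, problem):
        X, time, event = problem
        beta = lasso_cox(X, time, event, 0.0)
        fit = fit_cox(X, time, event)
        assert np.max(np.abs(beta - fit.beta)) < 1e-3

    @pytest.mark.parametrize("frac", [0.5, 0.2, 0.05])
    def test_matches_proximal_gradient_oracle(self, problem, frac):
        X, time, event = problem
        lam = frac * lambda_max(X, time, event)
        ours = lasso_cox(X, time, event, lam)
        oracle = ista_lasso_cox(X, time, event, lam)
        assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_matches_coxnet(self, problem):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        X, time, event = problem
        lam = 0.15 * lambda_max(X, time, event)
        ours = lasso_cox(X, time, event, lam)
        y = np.array(
            list(zip(event.astype(bool), time)),
            dtype=[("e", bool), ("t", float)],
        )
        m = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[lam], normalize=False, tol=1e-9,
            max_iter=100_000,
        ).fit(X, y)
        assert np.max(np.abs(ours - m.coef_.ravel())) < 1e-4

    def test_negative_lambda_rejected(self, problem):
        X, time, event = problem
        with pytest.raises(ValueError):
            lasso_cox(X, time, event, -0.1)

    def test_path_active_sets(self, problem):
        X, time, event = problem
        grid, betas = lambda_path(X, time, event, n_lambda=20)
        assert (betas[0] != 0).sum() == 0  # empty at lambda_max
        fit = fit_cox(X, time, event)
        strong = np.abs(fit.beta) > 0.1
        assert np.all(betas[-1][strong] != 0)  # recovered at smallest lambda


class TestCrossValidation:
    def test_deterministic(self, problem_cv):
        X, time, event = problem_cv
        a = lambda_path_cv(X, time, event, seed=11, n_lambda=15)
        b = lambda_path_cv(X, time, event, seed=11, n_lambda=15)
        assert np.array_equal(a["cv_loglik"], b["cv_loglik"])
        assert a["lambda_best"] == b["lambda_best"]

    def test_null_data_selects_sparse_model(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 60))
        _, time, event = make_ph_data(150, [0.0], seed=13)
        cv = lambda_path_cv(X, time, event, seed=14, n_lambda=25)
        assert (cv["beta_best"] != 0).sum() <= 5

    @pytest.fixture(scope="class")
    def problem_cv(self):
        X, time, event = make_ph_data(150, [0.6, -0.4, 0.3, 0.0], seed=10)
        return X, time, event


class TestBuildSignature:
    def test_recovers_signal_genes(self, small_cohort):
        expr, clinical, truth = small_cohort
        z, _ = fit_preprocess(expr)
        sig = build_signature(z, clinical, target_size=15, seed=20)
        recovered = set(sig.gene_ids) & set(truth.signal_gene_ids)
        assert len(recovered) >= 0.8 * len(truth.signal_gene_ids)

    def test_target_size_one_keeps_strongest_effect(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        sig = build_signature(z, clinical, target_size=1, seed=21)
        assert len(sig) == 1
        assert sig.lasso_beta[0] != 0

    def test_no_survivors_errors(self, null_cohort):
        expr, clinical, _ = null_cohort
        z, _ = fit_preprocess(expr)
        with pytest.raises(ValueError, match="alpha"):
            build_signature(z, clinical, alpha=1e-12, seed=22)

    def test_provenance_recorded(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        sig = build_signature(z, clinical, target_size=10, seed=23)
        assert sig.meta["mode"] == "target_size"
        assert sig.lambda_used > 0
        assert len(sig.uni_p) == len(sig)
        assert np.all(sig.lasso_beta != 0)
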