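"""Concordance, bootstrap CIs, IPCW time-dependent AUC, risk stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepcox import (
    TrainConfig,
    cindex_ci,
    concordance_index,
    dichotomize_risk,
    evaluate_cohort,
    fit_preprocess,
    logrank_test,
    time_dependent_auc,
    train_deepcox,
)
from tests.conftest import expr_from_array, make_ph_data


def brute_force_cindex(scores, time, event):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            )
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_discrimination(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        scores = -time  # higher score = earlier event
        assert concordance_index(scores, time, [1, 1, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert concordance_index(
            np.zeros(5), [1.0, 2, 3, 4, 5], [1, 1, 1, 1, 1]
        ) == 0.5

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 12
            time = np.round(rng.uniform(1, 6, n))
            event = rng.integers(0, 2, n)
            event[:2] = 1
            scores = np.round(rng.normal(size=n), 1)
            assert concordance_index(scores, time, event) == pytest.approx(
                brute_force_cindex(scores, time, event), abs=1e-12
            )

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index as ll_cindex

        scores, time, event = _scored_cohort(300, seed=1)
        ours = concordance_index(scores, time, event)
        # lifelines counts concordance for higher prediction = longer survival
        theirs = ll_cindex(time, -scores, event)
        assert ours == pytest.approx(theirs, abs=1e-12)

    @given(a=st.floats(0.01, 10), b=st.floats(-5, 5), seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_increasing_transform(self, a, b, seed):
        scores, time, event = _scored_cohort(60, seed=seed)
        c1 = concordance_index(scores, time, event)
        c2 = concordance_index(a * scores + b, time, event)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_uno_variant_matches_sksurv(self):
        from sksurv.metrics import concordance_index_ipcw

        scores, time, event = _scored_cohort(300, seed=15)
        tau = float(np.percentile(time, 80))
        y = np.array(
            list(zip(event.astype(bool), time)), dtype=[("e", bool), ("t", float)]
        )
        theirs = concordance_index_ipcw(y, y, scores, tau=tau)[0]
        ours = concordance_index(scores, time, event, method="uno", tau=tau)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1.0, 2.0], [5.0, 6.0], [0, 0])


def _scored_cohort(n, seed, beta=1.0):
    X, time, event = make_ph_data(n, [beta], seed=seed)
    return X[:, 0], time, event


class TestBootstrapCI:
    def test_deterministic_given_seed(self):
        scores, time, event = _scored_cohort(120, seed=2)
        a = cindex_ci(scores, time, event, n_boot=200, seed=3)
        b = cindex_ci(scores, time, event, n_boot=200, seed=3)
        assert a == b

    def test_brackets_point_and_narrow_with_signal(self):
        scores, time, event = _scored_cohort(500, seed=4)
        point, lo, hi = cindex_ci(scores, time, event, n_boot=400, seed=5)
        assert lo <= point <= hi
        assert hi - lo < 0.1

    def test_requires_enough_replicates(self):
        scores, time, event = _scored_cohort(50, seed=6)
        with pytest.raises(ValueError, match="200"):
            cindex_ci(scores, time, event, n_boot=50, seed=0)


class TestTimeDependentAUC:
    def test_perfect_separation_no_censoring(self):
        time = np.array([1.0, 2.0, 10.0, 20.0, 30.0])
        event = np.ones(5, dtype=int)
        scores = -time
        assert time_dependent_auc(scores, time, event, 5.0) == 1.0

    def test_reduces_to_binary_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        n = 400
        scores = rng.normal(size=n)
        time = np.maximum(rng.exponential(30, n) / np.exp(scores), 1e-9)
        event = np.ones(n, dtype=int)
        h = 20.0
        ours = time_dependent_auc(scores, time, event, h)
        theirs = roc_auc_score((time <= h).astype(int), scores)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        scores = rng.normal(size=n)  # independent of outcome
        time = np.maximum(rng.exponential(30, n), 1e-9)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        assert time_dependent_auc(scores, time, event, 25.0) == pytest.approx(
            0.5, abs=0.03
        )

    def test_score_negation_complements(self):
        scores, time, event = _scored_cohort(300, seed=9)
        a = time_dependent_auc(scores, time, event, 15.0)
        b = time_dependent_auc(-scores, time, event, 15.0)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_horizon_rejected(self):
        scores, time, event = _scored_cohort(50, seed=10)
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc(scores, time, event, float(time.max() + 1))


class TestDichotomize:
    def test_median_split(self):
        scores = np.arange(1.0, 11.0)
        labels, cutoff = dichotomize_risk(scores)
        assert cutoff == 5.5
        assert (labels == "high").sum() == 5

    def test_external_cutoff_can_degenerate(self):
        with pytest.warns(RuntimeWarning, match="high"):
            labels, _ = dichotomize_risk(np.array([5.0, 6.0, 7.0]), cutoff=1.0)
        assert set(labels) == {"high"}

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_risk(np.ones(4))

    def test_strong_signal_separates_survival(self):
        scores, time, event = _scored_cohort(500, seed=11)
        labels, _ = dichotomize_risk(scores)
        hi = labels == "high"
        _, p = logrank_test(time[hi], event[hi], time[~hi], event[~hi])
        assert p < 0.001


class TestEvaluateCohort:
    def test_composite_report(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        cl = clinical.aligned_to(z.sample_ids)
        model = train_deepcox(
            z.subset_genes(z.gene_ids[:20]), cl.time, cl.event,
            TrainConfig(max_epochs=30), seed=12,
        )
        rep = evaluate_cohort(
            model, z, clinical, horizons=[36.0], seed=13, n_boot=200,
            cohort="train",
        )
        assert 0 <= rep.c_index <= 1
        assert rep.c_index_ci[0] <= rep.c_index <= rep.c_index_ci[1]
        assert 36.0 in rep.auc_by_horizon
        assert rep.n == expr.n_samples
        assert "c_index" in rep.to_text()

    def test_km_plot_written(self, small_cohort, tmp_path):
        from tepcox.evaluation import plot_km_curves

        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        cl = clinical.aligned_to(z.sample_ids)
        model = train_deepcox(
            z.subset_genes(z.gene_ids[:10]), cl.time, cl.event,
            TrainConfig(max_epochs=10), seed=15,
        )
        rep = evaluate_cohort(model, z, clinical, seed=16, n_boot=200)
        plot_km_curves(rep, tmp_path / "km.png")
        assert (tmp_path / "km.png").stat().st_size > 0

    def test_empty_cohort_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        z, _ = fit_preprocess(expr)
        cl = clinical.aligned_to(z.sample_ids)
        model = train_deepcox(
            z.subset_genes(z.gene_ids[:10]), cl.time, cl.event,
            TrainConfig(max_epochs=5), seed=14,
        )
        empty = z.subset_samples([])
        with pytest.raises(ValueError, match="empty"):
            evaluate_cohort(model, empty, clinical)
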