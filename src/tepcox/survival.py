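"""Censored time-to-event primitives: Cox partial likelihood (Breslow ties),
Newton-Raphson fitting with Breslow baseline hazard, Kaplan-Meier curves and
the two-group log-rank test.

Everything downstream — univariate gene screening, the L1 path, the neural
risk model's loss — calls into this module so that a single tie-handling
convention (Breslow: tied event times share one risk-set denominator) is used
throughout. The Efron correction is available behind a flag on
:func:`fit_cox` for cross-checks but is never the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "KMCurve",
    "cox_partial_loglik",
    "cox_loglik_grad_eta",
    "fit_cox",
    "breslow_cumhaz",
    "km_curve",
    "logrank_test",
]


def _check_outcomes(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.all(np.isin(event, [0, 1])):
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


def _risk_set_logsumexp(eta_sorted: np.ndarray) -> np.ndarray:
    """log(sum_{j>=i} exp(eta_j)) for eta sorted by ascending time, stable."""
    c = eta_sorted.max()
    s = np.cumsum(np.exp(eta_sorted - c)[::-1])[::-1]
    return c + np.log(s)


def cox_partial_loglik(eta, time, event) -> float:
    """Breslow partial log-likelihood of risk scores ``eta``.

    l(eta) = sum_{i: event} [eta_i - log sum_{j: t_j >= t_i} exp(eta_j)],
    with tied event times sharing a single risk-set denominator. Requires at
    least one event.
    """
    time, event = _check_outcomes(time, event)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != time.shape:
        raise ValueError("eta must align with outcomes")
    if event.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    log_s = _risk_set_logsumexp(e)
    # tied times share the risk set anchored at the first index of the block
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    return float(np.sum(d * (e - log_s[first])))


def cox_loglik_grad_eta(eta, time, event):
    """Gradient of the Breslow partial log-likelihood with respect to eta.

    Returns ``(loglik, grad, diag_w)`` where ``grad[i] = d_i - r_i * A_i``
    with ``A_i = sum_{event times t_k <= t_i} d_k / S_k`` and ``diag_w`` is
    the diagonal of the negative Hessian, ``r_i*A_i - r_i^2*B_i`` with
    ``B_i = sum d_k / S_k^2``. Used by both the coordinate-descent L1 solver
    and the neural loss backward pass.
    """
    time, event = _check_outcomes(time, event)
    eta = np.asarray(eta, dtype=float)
    if event.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    n = len(time)
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    log_s = _risk_set_logsumexp(e)
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    # per-block event counts and denominators; center exponentials so the
    # shift-invariant products r*A and r^2*B stay in range
    c = e.max()
    d_at = np.bincount(first, weights=d, minlength=n)  # events per block start
    s_at = np.exp(log_s - c)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc_a = np.where(s_at > 0, d_at / s_at, 0.0)
        inc_b = np.where(s_at > 0, d_at / s_at**2, 0.0)
    a = np.cumsum(inc_a)  # A at sorted position i: event blocks with start <= i
    b = np.cumsum(inc_b)
    # a sample at sorted position i is at risk for every block start <= i,
    # but only blocks at its own time or earlier; block starts at first[i]
    # include position i, so take cumsum up to index first[i]'s block... the
    # cumulative sums above already advance only at block starts, and for a
    # sample in a block the relevant prefix ends at its block start:
    a_i = a[first]
    b_i = b[first]
    r = np.exp(e - c)
    grad_sorted = d - r * a_i
    w_sorted = r * a_i - (r**2) * b_i
    w_sorted = np.maximum(w_sorted, 0.0)
    loglik = float(np.sum(d * (e - log_s[first])))
    grad = np.empty(n)
    w = np.empty(n)
    grad[order] = grad_sorted
    w[order] = w_sorted
    return loglik, grad, w


def _cox_score_info(X, time, event, beta, ties="breslow"):
    """Score vector and observed information of the partial likelihood."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    Xs = X[order]
    eta = Xs @ beta
    eta = eta - eta.max()
    r = np.exp(eta)
    rx = Xs * r[:, None]
    rxx = np.einsum("ij,ik->ijk", Xs, Xs) * r[:, None, None]
    # suffix sums: risk set at time t_i is positions i..n-1 of a tied block
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum(rx[::-1], axis=0)[::-1]
    s2 = np.cumsum(rxx[::-1], axis=0)[::-1]
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dk = d[i:j].sum()
        if dk > 0:
            if ties == "breslow":
                xbar = s1[i] / s0[i]
                loglik += float(eta[i:j] @ d[i:j]) - dk * np.log(s0[i])
                score += (Xs[i:j] * d[i:j, None]).sum(axis=0) - dk * xbar
                info += dk * (s2[i] / s0[i] - np.outer(xbar, xbar))
            else:  # efron
                tied = np.flatnonzero(d[i:j] == 1) + i
                r_t = r[tied].sum()
                s1_t = rx[tied].sum(axis=0)
                s2_t = rxx[tied].sum(axis=0)
                for m in range(int(dk)):
                    f = m / dk
                    denom = s0[i] - f * r_t
                    xbar = (s1[i] - f * s1_t) / denom
                    loglik -= np.log(denom)
                    score -= xbar
                    info += (s2[i] - f * s2_t) / denom - np.outer(xbar, xbar)
                loglik += float(eta[tied].sum())
                score += Xs[tied].sum(axis=0)
        i = j
    return loglik, score, info


@dataclass
class CoxFit:
    """A fitted proportional-hazards model with Breslow baseline."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray  # cumulative hazard for covariates == 0
    n: int
    n_events: int
    converged: bool
    n_iter: int
    messages: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.beta - 1.959963984540054 * self.se)
        hi = np.exp(self.beta + 1.959963984540054 * self.se)
        return lo, hi

    @property
    def p_values(self) -> np.ndarray:
        z = np.divide(self.beta, self.se, out=np.zeros_like(self.beta),
                      where=self.se > 0)
        return 2 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def cumhaz_at(self, times) -> np.ndarray:
        """Baseline cumulative hazard H0(t) evaluated by step interpolation."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.baseline_times, times, side="right") - 1
        out = np.where(idx >= 0, self.baseline_cumhaz[np.maximum(idx, 0)], 0.0)
        return out

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t | x) = exp(-H0(t) * exp(x @ beta)); shape (n_samples, n_times)."""
        lp = self.linear_predictor(X)
        h0 = self.cumhaz_at(times)
        return np.exp(-np.outer(np.exp(lp), h0))

    def summary(self):
        import pandas as pd

        lo, hi = self.ci
        return pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "se": self.se,
                "HR": self.hr,
                "HR_low95": lo,
                "HR_high95": hi,
                "p": self.p_values,
            }
        )


def breslow_cumhaz(eta, time, event):
    """Breslow estimator of the baseline cumulative hazard.

    H0(t) = sum_{event times t_k <= t} d_k / sum_{j: t_j >= t_k} exp(eta_j),
    for a subject with eta = 0. Returns (distinct event times, H0 values).
    """
    time, event = _check_outcomes(time, event)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    r = np.exp(e)
    s0 = np.cumsum(r[::-1])[::-1]
    times, h = [], []
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dk = d[i:j].sum()
        if dk > 0:
            times.append(t[i])
            h.append(dk / s0[i])
        i = j
    return np.asarray(times), np.cumsum(h)


def fit_cox(
    X,
    time,
    event,
    names: list[str] | None = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson with step-halving.

    Parameters
    ----------
    X : (n, p) covariate matrix; constant columns raise.
    ties : 'breslow' (default) or 'efron'.
    tol : convergence on relative log-likelihood change; the gradient norm at
        the solution is additionally polished below 1e-6.
    """
    time, event = _check_outcomes(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != len(time):
        raise ValueError("X rows must align with outcomes")
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    if n <= p:
        raise ValueError(f"need more samples ({n}) than covariates ({p})")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        k = int(np.flatnonzero(sd == 0)[0])
        nm = names[k] if names else f"x{k}"
        raise ValueError(f"constant covariate {nm!r} carries no information")
    if names is None:
        names = [f"x{k}" for k in range(p)]

    beta = np.zeros(p)
    loglik, score, info = _cox_score_info(X, time, event, beta, ties)
    loglik_null = loglik
    messages: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll, new_score, new_info = _cox_score_info(X, time, event, cand, ties)
            if new_ll >= loglik - 1e-12:
                break
            scale /= 2
        improved = new_ll - loglik
        step_norm = scale * np.linalg.norm(step)
        beta, score, info = cand, new_score, new_info
        loglik = new_ll
        # quadratic convergence: a tiny Newton step bounds the beta error
        if np.linalg.norm(score) < 1e-9 or step_norm < 1e-11:
            converged = True
            break
        if abs(improved) < min(tol * (abs(loglik) + 1), 1e-13):
            converged = np.linalg.norm(score) < 1e-6
            break
    if np.any(np.abs(beta) * sd > 5):
        # the partial likelihood is monotone under a perfectly separated
        # risk ordering: the score vanishes as |beta| grows without bound
        k = int(np.argmax(np.abs(beta) * sd))
        messages.append(
            f"monotone partial likelihood suspected for {names[k]!r} "
            f"(standardized effect {abs(beta[k]) * sd[k]:.1f}); estimates "
            "unreliable"
        )
        converged = False
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)
    elif not converged:
        messages.append("Newton iteration limit reached before convergence")
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        messages.append("singular information matrix; standard errors undefined")
    bt, bh = breslow_cumhaz(X @ beta, time, event)
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=loglik,
        loglik_null=loglik_null,
        baseline_times=bt,
        baseline_cumhaz=bh,
        n=n,
        n_events=int(event.sum()),
        converged=converged,
        n_iter=it,
        messages=messages,
    )


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities outside [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def at(self, t) -> np.ndarray:
        """S(t) by right-continuous step interpolation (S = 1 before first event)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored-only times reduce the number at risk but add no step.
    """
    time, event = _check_outcomes(time, event)
    if len(time) == 0:
        raise ValueError("empty cohort")
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    n = len(t)
    times, surv, at_risk, events = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dk = d[i:j].sum()
        nk = n - i
        if dk > 0:
            s *= 1.0 - dk / nk
            times.append(t[i])
            surv.append(s)
            at_risk.append(nk)
            events.append(dk)
        i = j
    return KMCurve(
        times=np.asarray(times, dtype=float),
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=float),
        events=np.asarray(events, dtype=float),
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 degree of freedom.

    At each distinct event time the observed events in group A are compared
    with the expectation under the hypergeometric null given the margins.
    """
    ta, da = _check_outcomes(time_a, event_a)
    tb, db = _check_outcomes(time_b, event_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if da.sum() + db.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    t_all = np.concatenate([ta, tb])
    d_all = np.concatenate([da, db])
    g = np.concatenate([np.zeros(len(ta), dtype=int), np.ones(len(tb), dtype=int)])
    event_times = np.unique(t_all[d_all == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = t_all >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & (g == 0)).sum()
        d_tot = (d_all[(t_all == t)]).sum()
        d_a = (d_all[(t_all == t) & (g == 0)]).sum()
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += (
                d_tot
                * (n_a / n_tot)
                * (1 - n_a / n_tot)
                * (n_tot - d_tot)
                / (n_tot - 1)
            )
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
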