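"""Discrimination and stratification metrics for risk scores under censoring.

Harrell's concordance index (with bootstrap percentile CIs), the
cumulative-case / dynamic-control time-dependent AUC with
inverse-probability-of-censoring weights, training-median risk
dichotomization, and a cohort-level report composing them with Kaplan-Meier
curves and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._containers import ClinicalTable, ExpressionMatrix
from .network import DeepCoxModel, RiskScores, predict_risk
from .survival import KMCurve, _check_outcomes, km_curve, logrank_test

__all__ = [
    "concordance_index",
    "cindex_ci",
    "time_dependent_auc",
    "dichotomize_risk",
    "evaluate_cohort",
    "EvaluationReport",
]


def _scores_array(scores, n):
    s = scores.score if isinstance(scores, RiskScores) else np.asarray(scores, float)
    if len(s) != n:
        raise ValueError("scores must align with outcomes")
    return s


def concordance_index(scores, time, event, *, method: str = "harrell",
                      tau: float | None = None) -> float:
    """Concordance of risk scores with censored outcomes.

    ``method='harrell'`` (default): usable pairs (i, j) are t_i < t_j with
    event_i = 1, plus tied-time pairs with exactly one event (the
    event-bearing member must have the higher score); score ties credit
    1/2; returns concordant weight over usable pairs. Higher score must
    mean earlier event for a concordant pair.

    ``method='uno'``: the IPCW variant — pairs t_i < t_j (event_i = 1,
    t_i < tau) weighted 1/Ĝ(t_i⁻)², Ĝ the Kaplan-Meier estimate of the
    censoring distribution; unbiased for the population concordance
    truncated at ``tau`` (default: the largest event time) under heavier
    censoring than Harrell's C tolerates.
    """
    time, event = _check_outcomes(time, event)
    s = _scores_array(scores, len(time))
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None].astype(bool)
    e_j = event[None, :].astype(bool)
    usable = (t_i < t_j) & e_i
    if method == "harrell":
        usable |= (t_i == t_j) & e_i & ~e_j
        w = np.ones_like(time)
    elif method == "uno":
        if tau is None:
            tau = float(time[event == 1].max())
        usable &= t_i < tau
        g = _censoring_km(time, event)
        idx = np.searchsorted(g.times, time, side="left") - 1
        g_left = (
            np.where(idx >= 0, g.survival[np.maximum(idx, 0)], 1.0)
            if len(g.times)
            else np.ones_like(time)
        )
        w = 1.0 / g_left**2
    else:
        raise ValueError(f"unknown method {method!r}")
    s_i = s[:, None]
    s_j = s[None, :]
    wmat = np.where(usable, w[:, None], 0.0)
    den = wmat.sum()
    if den == 0:
        raise ValueError("no usable pairs (all censored or all tied times)")
    num = (wmat * (s_i > s_j)).sum() + 0.5 * (wmat * (s_i == s_j)).sum()
    return float(num / den)


def cindex_ci(
    scores,
    time,
    event,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Nonparametric bootstrap percentile CI for Harrell's C.

    Replicates without a usable pair are redrawn (warned when > 5% of
    draws). Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    time, event = _check_outcomes(time, event)
    s = _scores_array(scores, len(time))
    point = concordance_index(s, time, event)
    rng = np.random.default_rng(seed)
    n = len(time)
    vals = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = concordance_index(s[idx], time[idx], event[idx])
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("bootstrap could not find a replicate with usable pairs")
    if redraws > 0.05 * n_boot:
        warnings.warn(
            f"{redraws} bootstrap redraws due to degenerate replicates",
            RuntimeWarning,
            stacklevel=2,
        )
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi)


def _censoring_km(time, event) -> KMCurve:
    """KM estimate of the censoring survival G(t) (censorings as 'events')."""
    return km_curve(time, 1 - event)


def time_dependent_auc(scores, time, event, horizon: float) -> float:
    """Cumulative-case / dynamic-control AUC at ``horizon`` with IPCW.

    Cases: t_i <= horizon with an event, weighted 1/G(t_i-); controls:
    t_j > horizon, weighted 1/G(horizon); G is the Kaplan-Meier estimate of
    the censoring distribution. Score ties credit 1/2. With no censoring
    before the horizon all weights are equal and the estimate reduces to the
    plain binary AUC of score against event-by-horizon status.
    """
    time, event = _check_outcomes(time, event)
    s = _scores_array(scores, len(time))
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any() or not controls.any():
        raise ValueError(
            f"no cases or no controls at horizon {horizon} months"
        )
    g = _censoring_km(time, event)

    def g_left(t):
        # left limit G(t-): step strictly before t
        tt = np.atleast_1d(np.asarray(t, float))
        if len(g.times) == 0:
            return np.ones_like(tt)
        idx = np.searchsorted(g.times, tt, side="left") - 1
        return np.where(idx >= 0, g.survival[np.maximum(idx, 0)], 1.0)

    w_case = 1.0 / g_left(time[cases])
    w_ctrl = np.full(controls.sum(), 1.0 / g.at(horizon)[0])
    sc = s[cases][:, None]
    st = s[controls][None, :]
    wmat = w_case[:, None] * w_ctrl[None, :]
    num = (wmat * (sc > st)).sum() + 0.5 * (wmat * (sc == st)).sum()
    return float(num / wmat.sum())


def dichotomize_risk(scores, cutoff: float | None = None):
    """Split into low/high risk groups; default cutoff = median of scores.

    When evaluating a validation cohort, pass the *training* cutoff. Returns
    (labels, cutoff) with labels 'high' where score > cutoff.
    """
    s = scores.score if isinstance(scores, RiskScores) else np.asarray(scores, float)
    if np.all(s == s[0]):
        raise ValueError("all scores identical; cannot dichotomize")
    if cutoff is None:
        cutoff = float(np.median(s))
    labels = np.where(s > cutoff, "high", "low")
    if len(set(labels)) == 1:
        warnings.warn(
            f"every sample fell in the {labels[0]!r} group at cutoff {cutoff:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return labels, float(cutoff)


def plot_km_curves(report: "EvaluationReport", path) -> None:
    """Write a Kaplan-Meier plot of the low/high risk groups to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for km, label, color in [
        (report.km_low, "low risk", "#2166ac"),
        (report.km_high, "high risk", "#b2182b"),
    ]:
        if km is None:
            continue
        t = np.concatenate([[0.0], np.repeat(km.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]])
        ax.plot(t, s, label=label, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    title = f"{report.cohort or 'cohort'} ({report.endpoint.upper()})"
    if np.isfinite(report.logrank_p):
        title += f", log-rank p = {report.logrank_p:.2g}"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class EvaluationReport:
    """Cohort-level discrimination and stratification summary."""

    cohort: str
    endpoint: str
    n: int
    n_events: int
    c_index: float
    c_index_ci: tuple[float, float]
    auc_by_horizon: dict[float, float]
    risk_cutoff: float
    logrank_chi2: float
    logrank_p: float
    km_low: KMCurve | None = None
    km_high: KMCurve | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.c_index <= 1:
            raise ValueError("C-index outside [0, 1]")
        lo, hi = self.c_index_ci
        if not lo <= self.c_index <= hi:
            raise ValueError("CI must bracket the point estimate")

    def to_text(self) -> str:
        lines = [
            f"cohort: {self.cohort}",
            f"endpoint: {self.endpoint}",
            f"n: {self.n}",
            f"events: {self.n_events}",
            f"c_index: {self.c_index:.6f}",
            f"c_index_ci95: {self.c_index_ci[0]:.6f},{self.c_index_ci[1]:.6f}",
            f"risk_cutoff: {self.risk_cutoff!r}",
            f"logrank_chi2: {self.logrank_chi2:.6f}",
            f"logrank_p: {self.logrank_p:.6g}",
        ]
        for h, a in sorted(self.auc_by_horizon.items()):
            lines.append(f"auc_{h:g}mo: {a:.6f}")
        return "\n".join(lines) + "\n"


def evaluate_cohort(
    model: DeepCoxModel,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons=(36.0,),
    seed: int = 0,
    *,
    cutoff: float | None = None,
    n_boot: int = 1000,
    endpoint: str = "os",
    cohort: str = "",
) -> EvaluationReport:
    """Predict risk and compute the full report for one cohort.

    ``expr`` must already be transformed with the frozen training
    preprocessing. ``cutoff`` carries the training-derived risk cutoff to
    validation cohorts; when None the cohort's own median is used (training
    only). Horizons without both cases and controls are skipped with a
    warning rather than failing the whole report.
    """
    if expr.n_samples == 0:
        raise ValueError("empty cohort")
    clinical = clinical.aligned_to(expr.sample_ids)
    scores = predict_risk(model, expr)
    time, event = clinical.time, clinical.event
    point, lo, hi = cindex_ci(scores, time, event, n_boot=n_boot, seed=seed)
    lo, hi = min(lo, point), max(hi, point)
    aucs = {}
    for h in horizons:
        try:
            aucs[float(h)] = time_dependent_auc(scores, time, event, float(h))
        except ValueError as exc:
            warnings.warn(f"AUC skipped: {exc}", RuntimeWarning, stacklevel=2)
    labels, used_cutoff = dichotomize_risk(scores, cutoff)
    low, high = labels == "low", labels == "high"
    if low.any() and high.any():
        chi2, p = logrank_test(time[low], event[low], time[high], event[high])
        km_low = km_curve(time[low], event[low]) if event[low].any() else None
        km_high = km_curve(time[high], event[high]) if event[high].any() else None
    else:
        chi2, p, km_low, km_high = np.nan, np.nan, None, None
    return EvaluationReport(
        cohort=cohort,
        endpoint=endpoint,
        n=len(time),
        n_events=int(event.sum()),
        c_index=point,
        c_index_ci=(lo, hi),
        auc_by_horizon=aucs,
        risk_cutoff=used_cutoff,
        logrank_chi2=float(chi2),
        logrank_p=float(p),
        km_low=km_low,
        km_high=km_high,
        extras={"seed": seed, "scores": scores},
    )
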