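"""Independence analysis and nomogram construction.

``multivariable_adjustment`` fits a proportional-hazards model with the
neural risk score alongside the established clinical predictors (platelet
count, age, CA125, residual tumor, FIGO stage) to ask whether the score
carries independent prognostic information. ``build_nomogram`` converts a
fitted model into the standard regression-nomogram point system: each
covariate maps piecewise-linearly onto points (the covariate with the
largest |beta| * range spans exactly 0-100), total points map affinely back
onto the linear predictor, and the Breslow baseline turns the linear
predictor into survival probabilities at fixed horizons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._containers import ClinicalTable
from .network import RiskScores
from .survival import CoxFit, fit_cox

__all__ = [
    "multivariable_adjustment",
    "clinical_design",
    "NomogramSpec",
    "build_nomogram",
    "predict_from_nomogram",
]

CLINICAL_COVARIATES = ["platelet_count", "age", "ca125_log10", "residual", "stage"]


def clinical_design(clinical: ClinicalTable) -> pd.DataFrame:
    """Covariate frame for adjustment models.

    CA125 enters as log10 (its distribution is log-normal); FIGO stage as
    the ordinal 1-4; residual disease as the 0/1 indicator.
    """
    df = clinical.data
    out = pd.DataFrame(
        {
            "platelet_count": df["platelet_count"].astype(float),
            "age": df["age"].astype(float),
            "ca125_log10": np.log10(df["ca125"].astype(float)),
            "residual": df["residual"].astype(float),
            "stage": df["stage"].astype(float),
        }
    )
    return out


def multivariable_adjustment(
    scores: RiskScores,
    clinical: ClinicalTable,
    *,
    covariates: list[str] | None = None,
    condition_limit: float = 1e8,
) -> CoxFit:
    """Cox fit of the risk score plus clinical covariates.

    Raises on numerically collinear designs, naming the offending pair.
    """
    clinical = clinical.aligned_to(scores.sample_ids)
    design = clinical_design(clinical)
    covariates = covariates or CLINICAL_COVARIATES
    X = np.column_stack(
        [scores.score] + [design[c].to_numpy() for c in covariates]
    )
    names = ["risk_score", *covariates]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        k = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant covariate {names[k]!r}")
    Xs = (X - X.mean(axis=0)) / sd
    cond = np.linalg.cond(Xs)
    if cond > condition_limit:
        corr = np.corrcoef(Xs, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"collinear covariates (condition number {cond:.3g}): "
            f"{names[i]!r} vs {names[j]!r}"
        )
    return fit_cox(X, clinical.time, clinical.event, names=names)


@dataclass
class NomogramSpec:
    """Points system derived from a Cox fit.

    For covariate k with coefficient beta_k over declared range
    [lo_k, hi_k], points_k(x) = 100 * |beta_k| * (x - x_k*) / B where x_k*
    is the range end minimizing beta_k * x and B = max_k |beta_k| * range_k,
    so points are nonnegative and increase with hazard. The total-points
    axis maps affinely back to the linear predictor, and survival at each
    horizon comes from the fit's Breslow baseline.
    """

    names: list[str]
    beta: np.ndarray
    ranges: dict[str, tuple[float, float]]
    horizons: list[float]
    fit: CoxFit
    scale_b: float = field(init=False)
    lp_at_zero_points: float = field(init=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        spans = np.array(
            [abs(b) * (self.ranges[n][1] - self.ranges[n][0])
             for n, b in zip(self.names, self.beta)]
        )
        if np.all(spans == 0):
            raise ValueError("all covariates carry zero beta*range; no nomogram")
        self.scale_b = float(spans.max())
        self.lp_at_zero_points = float(
            sum(
                b * (self.ranges[n][0] if b >= 0 else self.ranges[n][1])
                for n, b in zip(self.names, self.beta)
            )
        )

    def points_for(self, name: str, value) -> np.ndarray:
        """Piecewise-linear covariate -> points map (clamped to the range)."""
        k = self.names.index(name)
        b = self.beta[k]
        lo, hi = self.ranges[name]
        v = np.clip(np.atleast_1d(np.asarray(value, float)), lo, hi)
        anchor = lo if b >= 0 else hi
        return 100.0 * abs(b) * np.abs(v - anchor) / self.scale_b

    def linear_predictor(self, total_points) -> np.ndarray:
        t = np.atleast_1d(np.asarray(total_points, float))
        return self.lp_at_zero_points + t * self.scale_b / 100.0

    def survival(self, total_points, horizon: float) -> np.ndarray:
        lp = self.linear_predictor(total_points)
        h0 = self.fit.cumhaz_at(horizon)[0]
        return np.exp(-h0 * np.exp(lp))

    def to_frame(self, n_grid: int = 11) -> pd.DataFrame:
        rows = []
        for name in self.names:
            lo, hi = self.ranges[name]
            for v in np.linspace(lo, hi, n_grid):
                rows.append(
                    {"variable": name, "value": v,
                     "points": float(self.points_for(name, v)[0])}
                )
        return pd.DataFrame(rows)


def build_nomogram(
    fit: CoxFit,
    horizons,
    ranges: dict[str, tuple[float, float]],
) -> NomogramSpec:
    """Nomogram from a converged Cox fit and declared covariate ranges."""
    if not fit.converged:
        warnings.warn(
            "building a nomogram from a non-converged fit", RuntimeWarning,
            stacklevel=2,
        )
    missing = [n for n in fit.names if n not in ranges]
    if missing:
        raise KeyError(f"no declared range for covariates {missing}")
    horizons = [float(h) for h in np.atleast_1d(horizons)]
    last = fit.baseline_times[-1] if len(fit.baseline_times) else 0.0
    for h in horizons:
        if h > last:
            raise ValueError(
                f"horizon {h} months exceeds the last event time ({last:.1f})"
            )
    return NomogramSpec(
        names=list(fit.names),
        beta=fit.beta.copy(),
        ranges={n: (float(lo), float(hi)) for n, (lo, hi) in ranges.items()},
        horizons=horizons,
        fit=fit,
    )


def predict_from_nomogram(spec: NomogramSpec, covariates: dict) -> dict[float, float]:
    """Survival probabilities per horizon for one covariate vector.

    Values outside the declared range are clamped with a warning. Missing
    covariates raise.
    """
    missing = [n for n in spec.names if n not in covariates]
    if missing:
        raise KeyError(f"missing covariates {missing}")
    total = 0.0
    for name in spec.names:
        v = float(covariates[name])
        lo, hi = spec.ranges[name]
        if v < lo or v > hi:
            warnings.warn(
                f"{name}={v:.4g} outside declared range [{lo:.4g}, {hi:.4g}]; "
                "clamped",
                RuntimeWarning,
                stacklevel=2,
            )
        total += float(spec.points_for(name, v)[0])
    return {h: float(spec.survival(total, h)[0]) for h in spec.horizons}
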