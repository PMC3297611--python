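"""Weibull survival curves on the model's 6-week-cycle time grid.

The decision model runs on an integer grid of 6-week cycles.  Every
survival quantity here is expressed in that unit: a Weibull law
``S(t) = exp(-scale * t**shape)`` with *t* in cycles, fitted trial curves
pooled into a patient-number-weighted reference, and hazard ratios applied
to the reference as ``S**HR`` (proportional hazards acting on the whole
curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape law of a survival curve, time in model cycles.

    ``scale`` is the Weibull rate parameter (lambda, units cycle^-shape)
    and ``shape`` the dimensionless gamma.  Standard errors and the
    scale/shape estimate correlation are carried along for probabilistic
    re-sampling of the curve.
    """

    scale: float
    shape: float
    se_scale: float = 0.0
    se_shape: float = 0.0
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")
        if not (self.shape > 0):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.se_scale < 0 or self.se_shape < 0:
            raise ValueError("standard errors must be non-negative")
        if abs(self.correlation) > 1:
            raise ValueError("correlation must lie in [-1, 1]")

    def median(self) -> float:
        """Analytic median survival time in cycles: (ln 2 / scale)^(1/shape)."""
        return (math.log(2.0) / self.scale) ** (1.0 / self.shape)


@dataclass(frozen=True)
class KMPoint:
    """One Kaplan-Meier summary point: time in cycles, survival fraction."""

    time: float
    survival: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError("survival must lie in [0, 1]")


@dataclass(frozen=True)
class TrialArm:
    """One trial's interferon-alfa arm: label, size and fitted PFS/OS laws."""

    label: str
    n_patients: int
    pfs_params: WeibullParams
    os_params: WeibullParams

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass(frozen=True)
class HazardRatio:
    """Hazard ratio with its 95% confidence interval."""

    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise ValueError("hazard ratios must be positive")
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("require ci_low <= mean <= ci_high")

    @property
    def log_sigma(self) -> float:
        """Normal sigma of ln(HR) implied by the 95% CI."""
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * 1.959963984540054)


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival fractions on integer cycles 0..H.

    Invariants: value 1 at cycle 0, values within [0, 1], non-increasing.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("curve must be a non-empty vector")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValueError("survival at cycle 0 must equal 1")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("survival values must be non-increasing")

    @property
    def horizon(self) -> int:
        return self.values.size - 1

    @property
    def cycle_grid(self) -> np.ndarray:
        return np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size


def eval_weibull(params: WeibullParams, t) -> float | np.ndarray:
    """Weibull survival fraction ``exp(-scale * t**shape)`` at time t (cycles)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.exp(-params.scale * t_arr ** params.shape)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def weibull_curve(params: WeibullParams, horizon: int) -> SurvivalCurve:
    """Evaluate a Weibull law on the integer cycle grid 0..horizon."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return SurvivalCurve(eval_weibull(params, np.arange(horizon + 1)))


@dataclass(frozen=True)
class WeibullFit:
    """fit_weibull result: estimates plus linearised-regression diagnostics."""

    params: WeibullParams
    adj_r2: float
    n_points: int


def fit_weibull(points: Sequence[KMPoint]) -> WeibullFit:
    """Least-squares Weibull fit on the complementary-log-log scale.

    Regresses ``ln(-ln S)`` on ``ln t``; the intercept is ln(scale) and the
    slope is the shape.  Points with survival exactly 0 or 1 (or t = 0)
    carry no information on this scale and are excluded.  Requires at least
    three usable points.  Standard errors for the scale are delta-method
    transformed from the intercept SE; the reported correlation is the
    estimated correlation of (ln-scale, shape), which is negative for
    ordinary survival data.
    """
    import statsmodels.api as sm

    usable = [p for p in points if 0.0 < p.survival < 1.0 and p.time > 0]
    if len(usable) < 3:
        raise ValueError(
            f"need at least 3 points with 0 < survival < 1 and t > 0, got {len(usable)}"
        )
    x = np.log([p.time for p in usable])
    y = np.log(-np.log([p.survival for p in usable]))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ln_scale, shape = res.params
    scale = math.exp(ln_scale)
    se_ln_scale, se_shape = res.bse
    cov = res.cov_params()
    denom = se_ln_scale * se_shape
    corr = float(cov[0, 1] / denom) if denom > 0 else 0.0
    # perfect fits leave adj-R2 as nan when residual variance underflows
    adj_r2 = float(res.rsquared_adj)
    if not np.isfinite(adj_r2):
        adj_r2 = 1.0
    params = WeibullParams(
        scale=scale,
        shape=float(shape),
        se_scale=scale * se_ln_scale,  # delta method: se(e^a) = e^a * se(a)
        se_shape=float(se_shape),
        correlation=max(-1.0, min(1.0, corr)),
    )
    return WeibullFit(params=params, adj_r2=adj_r2, n_points=len(usable))


def build_reference_curve(
    arms: Iterable[TrialArm], endpoint: str, horizon: int
) -> SurvivalCurve:
    """Patient-number-weighted average of the arms' Weibull curves.

    Produces the pooled "hypothetical average interferon-alfa" reference:
    per cycle t, sum_i w_i S_i(t) with w_i = n_i / sum(n).
    """
    arms = list(arms)
    if not arms:
        raise ValueError("need at least one trial arm")
    if endpoint not in ("PFS", "OS"):
        raise ValueError(f"endpoint must be 'PFS' or 'OS', got {endpoint!r}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    grid = np.arange(horizon + 1)
    total_n = sum(a.n_patients for a in arms)
    acc = np.zeros(horizon + 1)
    for a in arms:
        p = a.pfs_params if endpoint == "PFS" else a.os_params
        acc += (a.n_patients / total_n) * eval_weibull(p, grid)
    return SurvivalCurve(acc)


def apply_hr(reference: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Adjust a reference curve by a hazard ratio: pointwise S**hr.

    hr < 1 raises every interior point (better survival), hr > 1 lowers it;
    S(0) = 1 and monotonicity are preserved exactly.
    """
    if not hr > 0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return SurvivalCurve(reference.values ** hr)
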