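"""Three-state cohort trace and discounted life-year / QALY accumulation.

States: progression-free survival (PFS), progressed survival (PS), death.
Occupancy is read directly off the strategy's PFS and OS curves.  Two
constructions are supported:

* ``partitioned`` (default): occ_pfs = min(PFS, OS), occ_ps = max(OS-PFS, 0),
  occ_death = 1 - OS.  The standard partitioned-survival model; the min/max
  clipping handles curves that cross after hazard-ratio adjustment.
* ``competing``: occ_pfs = PFS * OS, occ_ps = OS * (1 - PFS).  A Markov
  variant in which death competes with progression inside the PFS state at
  the full OS hazard (so PFS-curve events and deaths are both counted as
  PFS exits).  It reproduces the reference-strategy occupancies of models
  that derive all transitions from the two curves independently.

Membership is counted at cycle start over cycles 0..H-1; a 6-week cycle
contributes 6/52 years.  A half-cycle correction is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survival import SurvivalCurve

#: years per 6-week model cycle
CYCLE_YEARS = 6.0 / 52.0

#: default model horizon: ceil(10 years / 6 weeks) = 87 cycles
DEFAULT_HORIZON = 87


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities for PFS and PS."""

    u_pfs: float
    u_ps: float

    def __post_init__(self) -> None:
        for u in (self.u_pfs, self.u_ps):
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utilities must lie in [0, 1], got {u}")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of a closed cohort (fractions summing to 1)."""

    occ_pfs: np.ndarray = field(repr=False)
    occ_ps: np.ndarray = field(repr=False)
    occ_death: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        total = self.occ_pfs + self.occ_ps + self.occ_death
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("state occupancies must sum to 1 at every cycle")
        if np.any(np.diff(self.occ_death) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occ_pfs.size


@dataclass(frozen=True)
class HealthOutcome:
    """Life-years and QALYs split by state (discounted unless noted)."""

    ly_pfs: float
    ly_ps: float
    qaly_pfs: float
    qaly_ps: float
    ly_pfs_undiscounted: float
    ly_ps_undiscounted: float

    @property
    def ly_total(self) -> float:
        return self.ly_pfs + self.ly_ps

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_ps

    @property
    def ly_total_undiscounted(self) -> float:
        return self.ly_pfs_undiscounted + self.ly_ps_undiscounted


def compute_trace(
    pfs: SurvivalCurve,
    os: SurvivalCurve,
    horizon: int = DEFAULT_HORIZON,
    state_model: str = "partitioned",
) -> CohortTrace:
    """Convert PFS and OS curves into a per-cycle three-state trace.

    Membership is evaluated at cycle start for cycles 0..horizon-1.
    """
    if len(pfs) != len(os):
        raise ValueError("PFS and OS curves must share the same cycle grid")
    if len(pfs) < horizon:
        raise ValueError(
            f"curves defined on {len(pfs)} cycles but horizon is {horizon}"
        )
    p = pfs.values[:horizon]
    o = os.values[:horizon]
    if state_model == "partitioned":
        occ_pfs = np.minimum(p, o)
        occ_ps = np.maximum(o - p, 0.0)
    elif state_model == "competing":
        occ_pfs = p * o
        occ_ps = o * (1.0 - p)
    else:
        raise ValueError(f"unknown state_model {state_model!r}")
    return CohortTrace(occ_pfs=occ_pfs, occ_ps=occ_ps, occ_death=1.0 - o)


def discount_factor(cycle, annual_rate: float):
    """Discount factor (1+r)^(-cycle*6/52); equals 1 at cycle 0."""
    c = np.asarray(cycle, dtype=float)
    if np.any(c < 0):
        raise ValueError("cycle must be non-negative")
    if annual_rate < 0:
        raise ValueError("annual_rate must be non-negative")
    out = (1.0 + annual_rate) ** (-c * CYCLE_YEARS)
    return float(out) if np.isscalar(cycle) else out


def discount_vector(n_cycles: int, annual_rate: float) -> np.ndarray:
    return discount_factor(np.arange(n_cycles), annual_rate)


def accumulate_outcomes(
    trace: CohortTrace,
    utilities: UtilitySet,
    annual_rate: float = 0.03,
    half_cycle: bool = False,
) -> HealthOutcome:
    """Sum state occupancy into (discounted) life-years and QALYs.

    ly_state = sum_t occ_state(t) * (6/52) * d(t); qaly_state = u * ly_state.
    With ``half_cycle`` the first cycle contributes half weight (trapezoid-
    style correction for counting membership at cycle start).
    """
    d = discount_vector(trace.n_cycles, annual_rate)
    w = np.ones(trace.n_cycles)
    if half_cycle:
        w[0] = 0.5
    ly_pfs = float(np.sum(trace.occ_pfs * w * d)) * CYCLE_YEARS
    ly_ps = float(np.sum(trace.occ_ps * w * d)) * CYCLE_YEARS
    return HealthOutcome(
        ly_pfs=ly_pfs,
        ly_ps=ly_ps,
        qaly_pfs=utilities.u_pfs * ly_pfs,
        qaly_ps=utilities.u_ps * ly_ps,
        ly_pfs_undiscounted=float(np.sum(trace.occ_pfs * w)) * CYCLE_YEARS,
        ly_ps_undiscounted=float(np.sum(trace.occ_ps * w)) * CYCLE_YEARS,
    )
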