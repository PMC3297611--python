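"""Direct medical costs per cycle and per strategy (2011 US dollars).

Costing conventions:

* Drug acquisition follows the whole-pack discard rule: packs per
  administration = ceil(dose / pack size), unused remainder discarded.
* Intravenous / subcutaneous administrations add a per-administration fee;
  oral drugs do not.
* First-line drug cost accrues over PFS occupancy only; the second-line /
  best-supportive-care mix accrues over PS occupancy; routine follow-up is
  charged in both states (restrictable to PFS by flag).
* Serious-adverse-event management is a one-off expected cost charged at
  model entry (per-patient event probabilities, not rates).
* A per-strategy dose-intensity factor scales first-line acquisition cost
  (it absorbs dose reductions, interruptions and price-unit ambiguity); a
  single second-line intensity factor does the same for the progressed
  state.  Both are explicit, documented calibration knobs.
* Under the sunitinib patient-assistance program (SPAP) patients pay for
  the first three treatment cycles and receive the drug free afterwards.
  The paid cycles are charged as three flat (occupancy-independent,
  discounted) cycle costs, mirroring the program's buy-in; second-line
  sunitinib is likewise only charged for the paid fraction
  3 / (mean second-line treatment duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CohortTrace, discount_vector
from .survival import HazardRatio

#: days in one model cycle
CYCLE_DAYS = 42

#: number of SPAP-funded (patient-paid) sunitinib cycles
SPAP_FUNDED_CYCLES = 3


@dataclass(frozen=True)
class UnitCost:
    """One price row: median with its deterministic sensitivity range."""

    item: str
    median: float
    low: float
    high: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.median <= self.high):
            raise ValueError(f"require 0 <= low <= median <= high for {self.item!r}")


class PriceTable(dict):
    """Mapping item -> UnitCost with attribute-style median lookup."""

    def price(self, item: str) -> float:
        try:
            return self[item].median
        except KeyError:
            raise KeyError(f"no unit cost for {item!r}") from None


@dataclass(frozen=True)
class DoseBlock:
    """A run of identical administrations within one cycle."""

    dose: float  # amount per administration, same unit as the pack size
    n_admin: int  # administrations at this dose in the cycle

    def __post_init__(self) -> None:
        if self.dose < 0 or self.n_admin < 0:
            raise ValueError("doses and administration counts must be non-negative")


@dataclass(frozen=True)
class DosingSchedule:
    """How one drug is given within a 6-week cycle.

    ``pack_size`` is the amount covered by one priced unit (the price-table
    row for ``price_item``); the discard rule rounds each administration up
    to whole packs.  ``first_cycle`` allows titration schedules that differ
    from steady state.
    """

    drug: str
    price_item: str
    pack_size: float
    route: str  # oral | iv | sc
    steady_cycle: tuple[DoseBlock, ...]
    first_cycle: tuple[DoseBlock, ...] | None = None

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv", "sc"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.pack_size <= 0:
            raise ValueError("pack_size must be positive")
        for blocks in (self.steady_cycle, self.first_cycle or ()):
            if sum(b.n_admin for b in blocks) > CYCLE_DAYS * 4:
                raise ValueError("administrations do not fit a 42-day cycle")

    def blocks_for_cycle(self, cycle_index: int) -> tuple[DoseBlock, ...]:
        if cycle_index == 0 and self.first_cycle is not None:
            return self.first_cycle
        return self.steady_cycle


def cycle_drug_cost(
    schedule: DosingSchedule,
    prices: PriceTable,
    cycle_index: int = 0,
    spap: bool = False,
    dose_intensity: float = 1.0,
    spap_eligible: bool = False,
) -> float:
    """Acquisition + administration cost of one drug for one cycle.

    Acquisition uses whole-pack rounding and is scaled by the dose-intensity
    factor; the iv/sc administration fee is charged per administration and
    is not intensity-scaled.  With ``spap`` and ``spap_eligible``,
    acquisition is free from the fourth cycle on.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    unit_price = prices.price(schedule.price_item)
    blocks = schedule.blocks_for_cycle(cycle_index)
    acquisition = 0.0
    n_admin = 0
    for b in blocks:
        packs = math.ceil(b.dose / schedule.pack_size - 1e-9) if b.dose > 0 else 0
        acquisition += packs * unit_price * b.n_admin
        n_admin += b.n_admin
    acquisition *= dose_intensity
    if spap and spap_eligible and cycle_index >= SPAP_FUNDED_CYCLES:
        acquisition = 0.0
    fee = 0.0
    if schedule.route in ("iv", "sc") and n_admin > 0:
        fee = n_admin * prices.price("drug_administration")
    return acquisition + fee


@dataclass(frozen=True)
class SAEProfile:
    """Grade >=3 adverse-event probabilities (per patient) by event name."""

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {name!r} outside [0, 1]")


def sae_expected_cost(profile: SAEProfile, prices: PriceTable) -> float:
    """One-off expected SAE management cost: sum p_event * unit cost."""
    return sum(
        p * prices.price(f"sae_{name}") for name, p in profile.probabilities.items()
    )


@dataclass(frozen=True)
class SecondLineMix:
    """Treatment mix of progressed patients.

    ``shares`` are absolute fractions of the progressed population on each
    second-line option (the remainder receives best supportive care with
    morphine).  ``cytokines`` is costed as an even split of the interferon
    and interleukin-2 steady-state cycles.
    """

    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, s in self.shares.items():
            if s < 0:
                raise ValueError(f"negative share for {name!r}")
        if sum(self.shares.values()) > 1.0 + 1e-9:
            raise ValueError("second-line shares sum above 1")

    @property
    def uptake(self) -> float:
        """Fraction of progressed patients on active second-line treatment."""
        return sum(self.shares.values())

    @property
    def bsc_share(self) -> float:
        return 1.0 - self.uptake


def ps_cycle_cost(
    mix: SecondLineMix,
    prices: PriceTable,
    schedules: Mapping[str, DosingSchedule],
    spap: bool = False,
    second_line_intensity: float = 1.0,
    spap_second_line_paid_fraction: float = 1.0,
    include_followup: bool = True,
) -> float:
    """Expected per-cycle cost of one progressed patient.

    Each second-line drug is costed by its steady-state cycle; under SPAP
    the second-line sunitinib acquisition is multiplied by the paid
    fraction 3 / (mean treatment duration in cycles).
    """

    def steady_cost(drug: str, intensity: float) -> float:
        sched = schedules[drug]
        return cycle_drug_cost(
            sched, prices, cycle_index=1, dose_intensity=intensity
        )

    total = 0.0
    for drug, share in mix.shares.items():
        if share == 0:
            continue
        intensity = second_line_intensity
        if drug == "cytokines":
            cost = 0.5 * (
                steady_cost("interferon", intensity) + steady_cost("interleukin2", intensity)
            )
        elif drug == "sunitinib" and spap:
            sched = schedules[drug]
            acq = cycle_drug_cost(sched, prices, 1, dose_intensity=intensity)
            cost = acq * spap_second_line_paid_fraction
        else:
            cost = steady_cost(drug, intensity)
        total += share * cost
    total += mix.bsc_share * steady_cost("morphine", 1.0)
    if include_followup:
        total += prices.price("followup")
    return total


@dataclass(frozen=True)
class StrategySpec:
    """One first-line treatment arm: effects, toxicity and dosing."""

    name: str
    hr_pfs: HazardRatio
    hr_os: HazardRatio
    first_line: tuple[str, ...]
    sae: SAEProfile
    dose_intensity: float = 1.0
    spap_eligible: bool = False  # sunitinib-containing first line


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted lifetime costs split by health state."""

    cost_pfs: float
    cost_ps: float

    def __post_init__(self) -> None:
        if self.cost_pfs < -1e-9 or self.cost_ps < -1e-9:
            raise ValueError("costs must be non-negative")

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_ps


def accumulate_costs(
    trace: CohortTrace,
    strategy: StrategySpec,
    prices: PriceTable,
    schedules: Mapping[str, DosingSchedule],
    mix: SecondLineMix,
    spap: bool = False,
    annual_rate: float = 0.03,
    second_line_intensity: float = 1.0,
    spap_second_line_paid_fraction: float = 1.0,
    followup_in_ps: bool = True,
    spap_charge: str = "flat",
) -> CostBreakdown:
    """Accrue a strategy's discounted lifetime costs over a cohort trace.

    cost_pfs = SAE one-off + sum_t occ_pfs(t) * (first-line drugs + follow-up) * d(t)
    cost_ps  = sum_t occ_ps(t) * ps_cycle_cost * d(t)

    Under SPAP with ``spap_charge='flat'`` the paid sunitinib cycles are
    charged as three full (occupancy-independent) discounted cycle costs;
    with ``'occupancy'`` they are weighted by PFS occupancy like any other
    drug cost.
    """
    n = trace.n_cycles
    d = discount_vector(n, annual_rate)

    pfs_cost = sae_expected_cost(strategy.sae, prices)
    for drug in strategy.first_line:
        sched = schedules[drug]
        eligible = strategy.spap_eligible and drug == "sunitinib"

        def cost_at(t: int) -> float:
            return cycle_drug_cost(
                sched, prices, t,
                spap=spap,
                dose_intensity=strategy.dose_intensity,
                spap_eligible=eligible,
            )

        # only three distinct cycle costs exist: titration cycle, steady
        # state, and (under SPAP) the donated phase
        per_cycle = np.full(n, cost_at(1))
        per_cycle[0] = cost_at(0)
        if spap and eligible:
            per_cycle[SPAP_FUNDED_CYCLES:] = cost_at(SPAP_FUNDED_CYCLES)
        if spap and eligible and spap_charge == "flat":
            # patients buy the first three cycles outright; afterwards the
            # drug is donated, so only administration fees (none for an
            # oral drug) follow occupancy
            paid = np.array(
                [
                    cycle_drug_cost(
                        sched, prices, t, dose_intensity=strategy.dose_intensity
                    )
                    for t in range(SPAP_FUNDED_CYCLES)
                ]
            )
            pfs_cost += float(np.sum(paid * d[:SPAP_FUNDED_CYCLES]))
            per_cycle = np.array(
                [
                    cycle_drug_cost(sched, prices, t, dose_intensity=0.0)
                    for t in range(n)
                ]
            )
        pfs_cost += float(np.sum(trace.occ_pfs * per_cycle * d))
    pfs_cost += float(np.sum(trace.occ_pfs * prices.price("followup") * d))

    psc = ps_cycle_cost(
        mix, prices, schedules,
        spap=spap,
        second_line_intensity=second_line_intensity,
        spap_second_line_paid_fraction=spap_second_line_paid_fraction,
        include_followup=followup_in_ps,
    )
    ps_cost = float(np.sum(trace.occ_ps * psc * d))
    return CostBreakdown(cost_pfs=pfs_cost, cost_ps=ps_cost)
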