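"""Cost-effectiveness frontier, ICERs and net health benefit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort import HealthOutcome
from .costing import CostBreakdown

ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"


@dataclass(frozen=True)
class StrategyResult:
    """One strategy's health outcome and cost breakdown."""

    name: str
    outcome: HealthOutcome
    costs: CostBreakdown

    @property
    def qaly(self) -> float:
        return self.outcome.qaly_total

    @property
    def cost(self) -> float:
        return self.costs.cost_total


@dataclass(frozen=True)
class FrontierStep:
    """One efficient strategy with its incremental cost per QALY."""

    name: str
    inc_cost: float
    inc_qaly: float
    icer: float | None  # None for the cheapest (anchor) strategy


@dataclass(frozen=True)
class FrontierResult:
    """Efficient frontier plus per-strategy dominance status."""

    frontier: tuple[FrontierStep, ...]
    status: dict[str, str]

    def icer_of(self, name: str) -> float | None:
        for step in self.frontier:
            if step.name == name:
                return step.icer
        return None


def icer_frontier(results: Sequence[StrategyResult]) -> FrontierResult:
    """Standard frontier algorithm with dominance and extended dominance.

    Sort by cost (ties toward the cheaper-listed strategy); drop strictly
    dominated strategies (another has <= cost and >= QALY, one strict);
    iteratively drop extended-dominated ones (a higher ICER than the next
    more effective frontier member); report pairwise ICERs between
    consecutive frontier members.
    """
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    status = {r.name: ON_FRONTIER for r in results}
    order = sorted(results, key=lambda r: (r.cost, -r.qaly))

    # strict dominance (identical points: the first-sorted one is retained)
    for i, r in enumerate(order):
        for other in order:
            if other is r or status[other.name] != ON_FRONTIER:
                continue
            if (
                other.cost <= r.cost
                and other.qaly >= r.qaly
                and (other.cost < r.cost or other.qaly > r.qaly)
            ):
                status[r.name] = DOMINATED
                break
            if (
                other.cost == r.cost
                and other.qaly == r.qaly
                and order.index(other) < i
            ):
                status[r.name] = DOMINATED
                break

    # extended dominance: ICERs must increase along the frontier
    while True:
        live = [r for r in order if status[r.name] == ON_FRONTIER]
        changed = False
        for i in range(1, len(live) - 1):
            icer_in = (live[i].cost - live[i - 1].cost) / (live[i].qaly - live[i - 1].qaly)
            icer_out = (live[i + 1].cost - live[i].cost) / (live[i + 1].qaly - live[i].qaly)
            if icer_in > icer_out:
                status[live[i].name] = EXTENDED_DOMINATED
                changed = True
                break
        if not changed:
            break

    live = [r for r in order if status[r.name] == ON_FRONTIER]
    steps = [FrontierStep(live[0].name, live[0].cost, live[0].qaly, None)]
    for prev, cur in zip(live, live[1:]):
        dc, dq = cur.cost - prev.cost, cur.qaly - prev.qaly
        steps.append(FrontierStep(cur.name, dc, dq, dc / dq))
    return FrontierResult(frontier=tuple(steps), status=status)


def net_health_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net health benefit in QALYs: dQ - dC / wtp."""
    if not wtp > 0:
        raise ValueError("willingness-to-pay must be positive")
    return delta_qaly - delta_cost / wtp
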