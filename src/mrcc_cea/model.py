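"""Deterministic decision model: curves -> trace -> outcomes -> costs.

``DecisionModel.evaluate`` re-runs the whole five-strategy model for an
arbitrary set of parameter overrides, which is the single entry point used
by the base case, the one-way sensitivity analysis and the probabilistic
sensitivity analysis.  Override keys:

========================  =====================================================
``hr_pfs.<strategy>``     PFS hazard ratio versus the interferon reference
``hr_os.<strategy>``      OS hazard ratio
``price.<item>``          unit cost (USD)
``sae.<strategy>.<evt>``  per-patient probability of a grade >=3 event
``utility.pfs|ps``        health-state utilities
``share.<drug>``          second-line mix share
``discount_rate``         annual discount rate
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

from .cohort import UtilitySet, accumulate_outcomes, compute_trace
from .config import ModelConfig
from .costing import (
    PriceTable,
    SAEProfile,
    SecondLineMix,
    UnitCost,
    accumulate_costs,
)
from .economics import FrontierResult, StrategyResult, icer_frontier
from .survival import apply_hr, build_reference_curve


def base_parameters(config: ModelConfig) -> dict[str, float]:
    """Flatten every overridable model input into a name -> value mapping."""
    params: dict[str, float] = {}
    for s in config.strategies:
        params[f"hr_pfs.{s.name}"] = s.hr_pfs.mean
        params[f"hr_os.{s.name}"] = s.hr_os.mean
        for event, p in s.sae.probabilities.items():
            params[f"sae.{s.name}.{event}"] = p
    for item, uc in config.prices.items():
        params[f"price.{item}"] = uc.median
    for drug, share in config.second_line.shares.items():
        params[f"share.{drug}"] = share
    params["utility.pfs"] = config.utilities.u_pfs
    params["utility.ps"] = config.utilities.u_ps
    params["discount_rate"] = config.engine.discount_rate
    return params


class DecisionModel:
    """The five-strategy partitioned-survival model for one configuration."""

    def __init__(self, config: ModelConfig):
        self.config = config
        h = config.engine.horizon
        self.reference_pfs = build_reference_curve(config.trials, "PFS", h)
        self.reference_os = build_reference_curve(config.trials, "OS", h)
        self._base = base_parameters(config)

    @property
    def parameters(self) -> dict[str, float]:
        return dict(self._base)

    def evaluate(
        self,
        spap: bool = False,
        overrides: Mapping[str, float] | None = None,
    ) -> list[StrategyResult]:
        """Run all strategies under (possibly overridden) parameters."""
        params = dict(self._base)
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown:
                raise KeyError(f"unknown model parameters: {sorted(unknown)}")
            params.update(overrides)

        cfg = self.config
        eng = cfg.engine
        rate = params["discount_rate"]
        utilities = UtilitySet(params["utility.pfs"], params["utility.ps"])

        prices = PriceTable()
        for item, uc in cfg.prices.items():
            v = params[f"price.{item}"]
            # sampled values may leave the deterministic range; widen it
            prices[item] = replace(
                uc, median=v, low=min(uc.low, v), high=max(uc.high, v)
            )
        mix = SecondLineMix(
            shares={d: params[f"share.{d}"] for d in cfg.second_line.shares}
        )

        results = []
        for strat in cfg.strategies:
            hp = params[f"hr_pfs.{strat.name}"]
            ho = params[f"hr_os.{strat.name}"]
            pfs = apply_hr(self.reference_pfs, hp)
            os_ = apply_hr(self.reference_os, ho)
            trace = compute_trace(pfs, os_, eng.horizon, eng.state_model)
            outcome = accumulate_outcomes(
                trace, utilities, rate, half_cycle=eng.half_cycle
            )
            sae = SAEProfile(
                {
                    e: params[f"sae.{strat.name}.{e}"]
                    for e in strat.sae.probabilities
                }
            )
            costs = accumulate_costs(
                trace,
                replace(strat, sae=sae),
                prices,
                cfg.dosing,
                mix,
                spap=spap,
                annual_rate=rate,
                second_line_intensity=eng.second_line_intensity,
                spap_second_line_paid_fraction=eng.spap_second_line_paid_fraction,
                followup_in_ps=eng.followup_in_ps,
                spap_charge=eng.spap_charge,
            )
            results.append(StrategyResult(name=strat.name, outcome=outcome, costs=costs))
        return results

    def run_base_case(
        self, spap: bool = False
    ) -> tuple[list[StrategyResult], FrontierResult]:
        results = self.evaluate(spap=spap)
        return results, icer_frontier(results)

    def pairwise(
        self,
        results: Sequence[StrategyResult],
        a: str,
        b: str,
    ) -> tuple[float, float]:
        """(delta cost, delta QALY) of strategy a versus strategy b."""
        by_name = {r.name: r for r in results}
        ra, rb = by_name[a], by_name[b]
        return ra.cost - rb.cost, ra.qaly - rb.qaly
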