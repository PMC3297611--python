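"""Deterministic (tornado) and probabilistic sensitivity analyses.

One-way analysis reruns the full deterministic model at each parameter's
low/high bound and reports the swing in incremental net health benefit.
The probabilistic analysis draws every uncertain parameter at once —
lognormal for costs (moment-matched to a 10% coefficient of variation),
beta for utilities and probabilities (same rule), lognormal for hazard
ratios with the sigma implied by their 95% CI — and re-evaluates the
cohort model per draw.  Acceptability curves report, per willingness-to-
pay threshold, the probability that each strategy has the greatest
monetary net benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import ModelConfig
from .economics import net_health_benefit
from .model import DecisionModel


@dataclass(frozen=True)
class ParamRange:
    """One uncertain input: deterministic bounds plus PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # lognormal | beta | fixed
    sd_rule: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.distribution not in ("lognormal", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    nhb_at_low: float
    nhb_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.nhb_at_high - self.nhb_at_low)


@dataclass(frozen=True)
class PsaSample:
    """One PSA draw: sampled parameters and per-strategy (cost, QALY)."""

    index: int
    parameters: dict[str, float] = field(repr=False)
    outcomes: dict[str, tuple[float, float]]  # name -> (cost, qaly)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy is optimal across WTP thresholds."""

    wtp_grid: np.ndarray = field(repr=False)
    probabilities: dict[str, np.ndarray] = field(repr=False)

    def at(self, wtp: float, strategy: str) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[idx] - wtp) > 1e-6 * max(1.0, wtp):
            raise KeyError(f"threshold {wtp} not on the CEAC grid")
        return float(self.probabilities[strategy][idx])


def build_ranges(config: ModelConfig) -> list[ParamRange]:
    """Assemble the uncertain-parameter set from a model configuration.

    Hazard ratios use their 95% CI bounds; unit costs their published
    ranges ('fixed' rows do not move deterministically but are still drawn
    in the PSA); adverse-event probabilities vary 90-110%; utilities use
    their published ranges; the discount rate moves 0-5% deterministically
    only.
    """
    sd = config.sensitivity.sd_fraction
    sae_frac = config.sensitivity.sae_range_fraction
    ranges: list[ParamRange] = []
    for s in config.strategies:
        for kind, hr in (("hr_pfs", s.hr_pfs), ("hr_os", s.hr_os)):
            if hr.ci_low == hr.ci_high == hr.mean:
                continue  # the reference strategy's HR is 1 by definition
            ranges.append(
                ParamRange(
                    name=f"{kind}.{s.name}",
                    base=hr.mean,
                    low=hr.ci_low,
                    high=hr.ci_high,
                    distribution="lognormal",
                    sd_rule="sigma from 95% CI",
                )
            )
        for event, p in s.sae.probabilities.items():
            if p == 0:
                continue
            ranges.append(
                ParamRange(
                    name=f"sae.{s.name}.{event}",
                    base=p,
                    low=(1 - sae_frac) * p,
                    high=(1 + sae_frac) * p,
                    distribution="beta",
                    sd_rule=f"sd = {sd:.0%} of mean",
                )
            )
    for item, uc in config.prices.items():
        ranges.append(
            ParamRange(
                name=f"price.{item}",
                base=uc.median,
                low=uc.median if uc.fixed else uc.low,
                high=uc.median if uc.fixed else uc.high,
                distribution="lognormal",
                sd_rule=f"sd = {sd:.0%} of mean",
            )
        )
    for drug, share in config.second_line.shares.items():
        ranges.append(
            ParamRange(
                name=f"share.{drug}",
                base=share,
                low=share,
                high=share,
                distribution="beta",
                sd_rule=f"sd = {sd:.0%} of mean",
            )
        )
    ut_bounds = {
        "pfs": (config.utilities.u_pfs, 0.26, 0.87),
        "ps": (config.utilities.u_ps, 0.19, 0.58),
    }
    for state, (base, low, high) in ut_bounds.items():
        ranges.append(
            ParamRange(
                name=f"utility.{state}",
                base=base,
                low=min(low, base),
                high=max(high, base),
                distribution="beta",
                sd_rule=f"sd = {sd:.0%} of mean",
            )
        )
    ranges.append(
        ParamRange(
            name="discount_rate",
            base=config.engine.discount_rate,
            low=config.sensitivity.discount_low,
            high=config.sensitivity.discount_high,
            distribution="fixed",
        )
    )
    return ranges


def one_way_dsa(
    model: DecisionModel,
    ranges: Sequence[ParamRange],
    pair: tuple[str, str],
    wtp: float,
    spap: bool = False,
) -> list[TornadoEntry]:
    """Tornado analysis of the incremental NHB of ``pair[0]`` vs ``pair[1]``."""
    entries = []
    for r in ranges:
        nhbs = []
        for value in (r.low, r.high):
            results = model.evaluate(spap=spap, overrides={r.name: value})
            dc, dq = model.pairwise(results, *pair)
            nhbs.append(net_health_benefit(dc, dq, wtp))
        entries.append(TornadoEntry(param=r.name, nhb_at_low=nhbs[0], nhb_at_high=nhbs[1]))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _beta_moments(mean: float, sd: float, name: str) -> tuple[float, float]:
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"beta moment matching infeasible for {name!r}: "
            f"sd {sd} too large for mean {mean}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_parameters(
    ranges: Sequence[ParamRange],
    rng: np.random.Generator,
    sd_fraction: float = 0.10,
) -> dict[str, float]:
    """Draw one parameter vector under the stated distributions."""
    out: dict[str, float] = {}
    for r in ranges:
        if r.distribution == "fixed" or r.base == 0 or sd_fraction == 0:
            out[r.name] = r.base
            continue
        if r.distribution == "lognormal":
            if r.name.startswith(("hr_pfs.", "hr_os.")):
                sigma = (math.log(r.high) - math.log(r.low)) / (2 * 1.959963984540054)
                out[r.name] = float(rng.lognormal(math.log(r.base), sigma))
            else:
                mu, sigma = _lognormal_moments(r.base, sd_fraction * r.base)
                out[r.name] = float(rng.lognormal(mu, sigma))
        elif r.distribution == "beta":
            a, b = _beta_moments(r.base, sd_fraction * r.base, r.name)
            out[r.name] = float(rng.beta(a, b))
    return out


def run_psa(
    model: DecisionModel,
    n_iter: int | None = None,
    seed: int | None = None,
    spap: bool = False,
    ranges: Sequence[ParamRange] | None = None,
) -> list[PsaSample]:
    """Monte-Carlo re-evaluation of the cohort model.

    Each iteration draws one full parameter vector and reruns all
    strategies; the cohort model is patient-count invariant, so one
    deterministic run per draw represents the simulated cohort.
    """
    cfg = model.config
    n_iter = cfg.sensitivity.n_iterations if n_iter is None else n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seed = cfg.sensitivity.seed if seed is None else seed
    ranges = build_ranges(cfg) if ranges is None else ranges
    master = np.random.SeedSequence(seed)
    samples = []
    for i, child in enumerate(master.spawn(n_iter)):
        rng = np.random.default_rng(child)
        params = sample_parameters(ranges, rng, cfg.sensitivity.sd_fraction)
        results = model.evaluate(spap=spap, overrides=params)
        samples.append(
            PsaSample(
                index=i,
                parameters=params,
                outcomes={r.name: (r.cost, r.qaly) for r in results},
            )
        )
    return samples


def ceac(samples: Sequence[PsaSample], wtp_grid: Sequence[float]) -> CeacCurve:
    """Cost-effectiveness acceptability curves from PSA samples.

    At each threshold, the probability that each strategy has the maximum
    monetary net benefit (wtp * QALY - cost); exact ties split equally.
    """
    if not samples:
        raise ValueError("no PSA samples")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    names = list(samples[0].outcomes)
    costs = np.array([[s.outcomes[n][0] for n in names] for s in samples])
    qalys = np.array([[s.outcomes[n][1] for n in names] for s in samples])
    probs = {n: np.zeros(grid.size) for n in names}
    for j, wtp in enumerate(grid):
        nmb = wtp * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9
        weights = winners / winners.sum(axis=1, keepdims=True)
        mean_w = weights.mean(axis=0)
        for k, n in enumerate(names):
            probs[n][j] = mean_w[k]
    return CeacCurve(wtp_grid=grid, probabilities=probs)


def pairwise_ce_probability(
    samples: Sequence[PsaSample], a: str, b: str, wtp: float
) -> float:
    """P(strategy a is cost-effective versus b at wtp), dominance included.

    Counts draws where a's monetary net benefit exceeds b's, i.e. the
    pairwise ICER falls below the threshold or a dominates b.
    """
    if not samples:
        raise ValueError("no PSA samples")
    wins = 0.0
    for s in samples:
        ca, qa = s.outcomes[a]
        cb, qb = s.outcomes[b]
        diff = wtp * (qa - qb) - (ca - cb)
        wins += 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
    return wins / len(samples)


def province_table(
    samples: Sequence[PsaSample],
    gdp_per_capita: Mapping[str, float],
    gdp_multiple: float = 3.0,
):
    """Acceptability (%) of each strategy at 3x regional per-capita GDP."""
    import pandas as pd

    thresholds = {region: gdp_multiple * g for region, g in gdp_per_capita.items()}
    curve = ceac(samples, list(thresholds.values()))
    rows = {}
    for region, wtp in thresholds.items():
        rows[region] = {
            "gdp": gdp_per_capita[region],
            "threshold": wtp,
            **{
                name: 100.0 * curve.at(wtp, name)
                for name in curve.probabilities
            },
        }
    return pd.DataFrame.from_dict(rows, orient="index")
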