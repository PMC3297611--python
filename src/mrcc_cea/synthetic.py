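"""Pseudo-individual-patient survival data from known Weibull laws.

Stands in for trial Kaplan-Meier data so curve fitting and parameter
recovery are testable end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survival import KMPoint, WeibullParams


@dataclass(frozen=True)
class PseudoIPD:
    """Per-patient event/censoring times in cycles with event indicators."""

    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)  # True = event, False = censored

    def __post_init__(self) -> None:
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must align")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")

    def __len__(self) -> int:
        return self.times.size


def generate_ipd(
    params: WeibullParams,
    n: int,
    censor_horizon: float | None = None,
    seed: int | np.random.Generator = 0,
) -> PseudoIPD:
    """Draw n event times by inverse-CDF sampling, t = (-ln U / scale)^(1/shape).

    Times beyond ``censor_horizon`` are administratively censored there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t = (-np.log(u) / params.scale) ** (1.0 / params.shape)
    if censor_horizon is None:
        return PseudoIPD(times=t, events=np.ones(n, dtype=bool))
    if censor_horizon < 0:
        raise ValueError("censor_horizon must be non-negative")
    events = t <= censor_horizon
    return PseudoIPD(times=np.minimum(t, censor_horizon), events=events)


def km_estimate(ipd: PseudoIPD) -> list[KMPoint]:
    """Product-limit survival estimate at the observed event times."""
    if len(ipd) == 0:
        raise ValueError("empty dataset")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    out = []
    for t, s in zip(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()):
        if t > 0:
            out.append(KMPoint(time=float(t), survival=float(s)))
    return out
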