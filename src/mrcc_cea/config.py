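"""Model configuration: schema, validation and the shipped default.

The whole evidence base of the analysis — trial Weibull fits, hazard
ratios, adverse-event probabilities, unit costs, dosing schedules, the
second-line mix, utilities, engine settings and the regional GDP table —
lives in one YAML document so every number is inspectable and overridable.
``load_default_config()`` returns the packaged base case.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import UtilitySet
from .costing import (
    DoseBlock,
    DosingSchedule,
    PriceTable,
    SAEProfile,
    SecondLineMix,
    StrategySpec,
    UnitCost,
)
from .survival import HazardRatio, TrialArm, WeibullParams

_TOP_KEYS = {
    "trials",
    "strategies",
    "prices",
    "dosing",
    "second_line",
    "utilities",
    "engine",
    "sensitivity",
    "regions",
}


class ConfigError(ValueError):
    """Raised with the offending field path when validation fails."""


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")


def _weibull(d: Mapping[str, Any], path: str) -> WeibullParams:
    _check_keys(d, {"scale", "se_scale", "shape", "se_shape", "correlation"}, path)
    try:
        return WeibullParams(
            scale=float(d["scale"]),
            shape=float(d["shape"]),
            se_scale=float(d.get("se_scale", 0.0)),
            se_shape=float(d.get("se_shape", 0.0)),
            correlation=float(d.get("correlation", 0.0)),
        )
    except (KeyError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def _hr(d: Mapping[str, Any], path: str) -> HazardRatio:
    _check_keys(d, {"mean", "ci_low", "ci_high"}, path)
    try:
        return HazardRatio(float(d["mean"]), float(d["ci_low"]), float(d["ci_high"]))
    except (KeyError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


@dataclass(frozen=True)
class EngineSettings:
    horizon: int = 87
    discount_rate: float = 0.03
    state_model: str = "partitioned"  # or "competing"
    half_cycle: bool = False
    followup_in_ps: bool = True
    spap_charge: str = "flat"  # or "occupancy"
    second_line_intensity: float = 1.0
    spap_second_line_paid_fraction: float = 1.0
    wtp: float = 13290.0


@dataclass(frozen=True)
class SensitivitySettings:
    n_iterations: int = 1000
    sd_fraction: float = 0.10
    sae_range_fraction: float = 0.10
    discount_low: float = 0.0
    discount_high: float = 0.05
    seed: int = 20110101


@dataclass(frozen=True)
class ModelConfig:
    trials: tuple[TrialArm, ...]
    strategies: tuple[StrategySpec, ...]
    prices: PriceTable
    dosing: Mapping[str, DosingSchedule]
    second_line: SecondLineMix
    utilities: UtilitySet
    engine: EngineSettings
    sensitivity: SensitivitySettings
    regions: Mapping[str, float]  # region -> per-capita GDP (USD)
    raw: dict = field(repr=False, compare=False, default_factory=dict)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def parse_config(doc: Mapping[str, Any]) -> ModelConfig:
    _check_keys(doc, _TOP_KEYS, "config")

    trials = []
    for name, td in doc["trials"].items():
        path = f"trials.{name}"
        _check_keys(td, {"n_patients", "pfs", "os"}, path)
        trials.append(
            TrialArm(
                label=name,
                n_patients=int(td["n_patients"]),
                pfs_params=_weibull(td["pfs"], f"{path}.pfs"),
                os_params=_weibull(td["os"], f"{path}.os"),
            )
        )

    prices = PriceTable()
    for item, pd in doc["prices"].items():
        path = f"prices.{item}"
        _check_keys(pd, {"median", "low", "high", "fixed"}, path)
        median = float(pd["median"])
        fixed = bool(pd.get("fixed", False))
        try:
            prices[item] = UnitCost(
                item=item,
                median=median,
                low=float(pd.get("low", median)),
                high=float(pd.get("high", median)),
                fixed=fixed,
            )
        except ValueError as e:
            raise ConfigError(f"{path}: {e}") from e

    dosing = {}
    for drug, dd in doc["dosing"].items():
        path = f"dosing.{drug}"
        _check_keys(dd, {"price_item", "pack_size", "route", "steady", "first"}, path)
        if dd["price_item"] not in prices:
            raise ConfigError(f"{path}.price_item: no price for {dd['price_item']!r}")

        def blocks(key: str) -> tuple[DoseBlock, ...] | None:
            if key not in dd:
                return None
            return tuple(
                DoseBlock(dose=float(b["dose"]), n_admin=int(b["n"])) for b in dd[key]
            )

        dosing[drug] = DosingSchedule(
            drug=drug,
            price_item=dd["price_item"],
            pack_size=float(dd["pack_size"]),
            route=dd["route"],
            steady_cycle=blocks("steady"),
            first_cycle=blocks("first"),
        )

    strategies = []
    for name, sd in doc["strategies"].items():
        path = f"strategies.{name}"
        _check_keys(
            sd, {"hr_pfs", "hr_os", "first_line", "sae", "dose_intensity"}, path
        )
        first_line = tuple(sd["first_line"])
        for drug in first_line:
            if drug not in dosing:
                raise ConfigError(f"{path}.first_line: no dosing schedule for {drug!r}")
        strategies.append(
            StrategySpec(
                name=name,
                hr_pfs=_hr(sd["hr_pfs"], f"{path}.hr_pfs"),
                hr_os=_hr(sd["hr_os"], f"{path}.hr_os"),
                first_line=first_line,
                sae=SAEProfile({k: float(v) for k, v in sd["sae"].items()}),
                dose_intensity=float(sd.get("dose_intensity", 1.0)),
                spap_eligible="sunitinib" in first_line,
            )
        )

    sl = doc["second_line"]
    _check_keys(sl, {"shares"}, "second_line")
    for drug in sl["shares"]:
        if drug not in dosing and drug != "cytokines":
            raise ConfigError(f"second_line.shares: no dosing schedule for {drug!r}")
    mix = SecondLineMix(shares={k: float(v) for k, v in sl["shares"].items()})

    ut = doc["utilities"]
    _check_keys(ut, {"pfs", "ps"}, "utilities")
    utilities = UtilitySet(u_pfs=float(ut["pfs"]), u_ps=float(ut["ps"]))
    if utilities.u_ps > utilities.u_pfs:
        raise ConfigError("utilities: progressed-state utility exceeds PFS utility")

    eng = dict(doc.get("engine", {}))
    _check_keys(eng, set(EngineSettings.__dataclass_fields__), "engine")
    engine = EngineSettings(**eng)
    if engine.state_model not in ("partitioned", "competing"):
        raise ConfigError(f"engine.state_model: unknown model {engine.state_model!r}")
    if engine.spap_charge not in ("flat", "occupancy"):
        raise ConfigError(f"engine.spap_charge: unknown mode {engine.spap_charge!r}")

    sens = dict(doc.get("sensitivity", {}))
    _check_keys(sens, set(SensitivitySettings.__dataclass_fields__), "sensitivity")

    regions = {str(k): float(v) for k, v in doc.get("regions", {}).items()}

    return ModelConfig(
        trials=tuple(trials),
        strategies=tuple(strategies),
        prices=prices,
        dosing=dosing,
        second_line=mix,
        utilities=utilities,
        engine=engine,
        sensitivity=SensitivitySettings(**sens),
        regions=regions,
        raw=json.loads(json.dumps(doc)),
    )


def load_config(path: str | Path) -> ModelConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


def load_default_config() -> ModelConfig:
    """The packaged 2011 Chinese-setting base case."""
    text = resources.files("mrcc_cea.data").joinpath("mrcc_2011.yaml").read_text()
    return parse_config(yaml.safe_load(text))
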