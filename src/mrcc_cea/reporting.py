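"""Result tables, delimited-text exports and the run manifest."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig
from .economics import FrontierResult, StrategyResult
from .model import DecisionModel
from .sensitivity import CeacCurve, PsaSample, TornadoEntry
from .survival import KMPoint, SurvivalCurve, apply_hr


def base_case_table(
    results: Sequence[StrategyResult], frontier: FrontierResult
) -> pd.DataFrame:
    """Strategy-by-outcome table mirroring the base-case results layout."""
    rows = {}
    for r in results:
        o = r.outcome
        rows[r.name] = {
            "cost_pfs": r.costs.cost_pfs,
            "cost_ps": r.costs.cost_ps,
            "cost_total": r.cost,
            "ly_pfs": o.ly_pfs,
            "ly_ps": o.ly_ps,
            "ly_total": o.ly_total,
            "ly_pfs_undiscounted": o.ly_pfs_undiscounted,
            "ly_ps_undiscounted": o.ly_ps_undiscounted,
            "ly_total_undiscounted": o.ly_total_undiscounted,
            "qaly_pfs": o.qaly_pfs,
            "qaly_ps": o.qaly_ps,
            "qaly_total": o.qaly_total,
            "cer": r.cost / o.qaly_total,
            "icer_frontier": frontier.icer_of(r.name),
            "status": frontier.status[r.name],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def curves_table(model: DecisionModel) -> pd.DataFrame:
    """Per-cycle adjusted PFS/OS survival fractions for every strategy."""
    cols = {"cycle": model.reference_pfs.cycle_grid}
    for s in model.config.strategies:
        cols[f"pfs_{s.name}"] = apply_hr(model.reference_pfs, s.hr_pfs.mean).values
        cols[f"os_{s.name}"] = apply_hr(model.reference_os, s.hr_os.mean).values
    return pd.DataFrame(cols)


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.param,
                "nhb_at_low": e.nhb_at_low,
                "nhb_at_high": e.nhb_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


def psa_table(samples: Sequence[PsaSample]) -> pd.DataFrame:
    """Cost/QALY pairs per draw and strategy (CE-plane data)."""
    rows = []
    for s in samples:
        for name, (cost, qaly) in s.outcomes.items():
            rows.append({"draw": s.index, "strategy": name, "cost": cost, "qaly": qaly})
    return pd.DataFrame(rows)


def ceac_table(curve: CeacCurve) -> pd.DataFrame:
    out = {"wtp": curve.wtp_grid}
    out.update(curve.probabilities)
    return pd.DataFrame(out)


def read_km_points(path: str | Path) -> list[KMPoint]:
    """Read Kaplan-Meier summary data: delimited text with columns
    time_cycles, survival."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        t_col, s_col = cols["time_cycles"], cols["survival"]
    except KeyError:
        raise ValueError(
            f"{path}: expected columns 'time_cycles' and 'survival', got {list(df.columns)}"
        ) from None
    return [
        KMPoint(time=float(t), survival=float(s))
        for t, s in zip(df[t_col], df[s_col])
    ]


def write_manifest(
    out_dir: Path, config: ModelConfig, seed: int, extra: dict | None = None
) -> Path:
    manifest = {
        "package": "mrcc-cea",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest.update(extra or {})
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
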