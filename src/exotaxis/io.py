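"""Tidy CSV/JSON output: sweep tables, trajectories, run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import ScenarioConfig
from .engine import EnsembleSummary, SweepResult, Trajectory

__all__ = [
    "write_sweep_csv",
    "write_ensemble_csv",
    "write_trajectory_csv",
    "write_metadata",
]


def write_sweep_csv(result: SweepResult, path: str | Path) -> Path:
    """One row per sweep point: parameter, value, mean velocity, SD, SEM."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(path, index=False)
    return path


def write_ensemble_csv(summary: EnsembleSummary, path: str | Path) -> Path:
    """One row per run: seed and its mean velocity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "run": range(summary.n_runs),
            "seed": [summary.base_seed + i for i in range(summary.n_runs)],
            "velocity": summary.velocities,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "t": traj.times,
        "x_f": traj.follower[:, 0],
        "y_f": traj.follower[:, 1],
    }
    if traj.leader is not None:
        data["x_l"] = traj.leader[:, 0]
        data["y_l"] = traj.leader[:, 1]
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def write_metadata(
    config: ScenarioConfig, path: str | Path, **extra
) -> Path:
    """JSON sidecar: resolved config, its hash, code version, extras."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "exotaxis_version": __version__,
    }
    payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
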