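"""CSV/YAML readers and writers (UTF-8, comma-separated, '.' decimal).

Every writer has a paired reader and the pair round-trips values
losslessly (floats are written in shortest-repr form).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from mdoe.calibration import MeasurementDataset, ParameterEnsemble
from mdoe.design import Design, DesignSpace, Factor
from mdoe.errors import ConfigurationError
from mdoe.model import Trajectory


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Trajectory CSV: time_h, states, per-feed flows and (if gas totals
    are tracked) the windowed respiratory quotient."""
    frame = traj.data
    if "nO2_mol" in frame.columns and "RQ" not in frame.columns:
        from mdoe.model import respiratory_quotient

        frame = frame.copy()
        frame["RQ"] = respiratory_quotient(traj, window=1.0)["RQ"].to_numpy()
    frame.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_dataset(d: MeasurementDataset, path: str | Path) -> None:
    d.observations.to_csv(path, index=False)


def read_dataset(
    path: str | Path,
    initial: dict[str, tuple[float, float]] | None = None,
    setpoints: dict[str, tuple[float, float]] | None = None,
) -> MeasurementDataset:
    obs = pd.read_csv(path, float_precision="round_trip")
    return MeasurementDataset(
        observations=obs, initial=initial or {}, setpoints=setpoints or {}
    )


def write_design(design: Design, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path: str | Path, space: DesignSpace) -> Design:
    frame = pd.read_csv(path, float_precision="round_trip")
    points = frame[space.names].to_numpy()
    return Design(space=space, points=points, n_random=0, seed=0)


def write_ensemble(ens: ParameterEnsemble, members_path: str | Path, summary_path: str | Path) -> None:
    ens.members.to_csv(members_path, index=False)
    ens.quantiles().rename_axis("parameter").to_csv(summary_path)


def read_ensemble(members_path: str | Path, bounds: dict[str, tuple[float, float]]) -> ParameterEnsemble:
    members = pd.read_csv(members_path, float_precision="round_trip")
    n = len(members)
    return ParameterEnsemble(
        members=members,
        rmsd=np.full(n, np.nan),
        converged=np.ones(n, dtype=bool),
        bounds=bounds,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a study configuration from YAML (JSON is valid YAML)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return cfg


def write_run_log(log: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
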