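"""Config files, trajectory export, and run manifests.

Configs are flat TOML with ``[model]`` and ``[run]`` tables mapping directly
onto :class:`~wcplast.params.ModelParams` and
:class:`~wcplast.params.RunSettings` fields.  Trajectories export to long
CSV (time, unit, E, I) with a JSON sidecar carrying parameters and seed, or
to an HDF5 container for full-rate weight series.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Trajectory
from .params import ModelParams, RunSettings

__all__ = [
    "load_config",
    "save_config",
    "trajectory_to_frame",
    "save_trajectory_csv",
    "save_trajectory_hdf5",
    "write_manifest",
]


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def save_config(path, params: ModelParams, settings: RunSettings) -> None:
    """Write a flat key-value TOML config with [model] and [run] tables."""
    lines = ["[model]"]
    lines += [f"{k} = {_toml_value(v)}" for k, v in dataclasses.asdict(params).items()]
    lines += ["", "[run]"]
    lines += [f"{k} = {_toml_value(v)}" for k, v in dataclasses.asdict(settings).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> tuple[ModelParams, RunSettings]:
    """Read a TOML config; missing keys fall back to defaults."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    params = ModelParams(**doc.get("model", {}))
    settings = RunSettings(**doc.get("run", {}))
    return params, settings


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format activity table: one row per (time, unit)."""
    n_samples, N = traj.E_series.shape
    return pd.DataFrame({
        "time": np.repeat(traj.times, N),
        "unit": np.tile(np.arange(1, N + 1), n_samples),
        "E": traj.E_series.ravel(),
        "I": traj.I_series.ravel(),
    })


def _sidecar(traj: Trajectory) -> dict:
    return {
        "seed": traj.seed,
        "drive_onset_s": traj.drive_onset,
        "model": dataclasses.asdict(traj.params),
        "run": dataclasses.asdict(traj.settings),
    }


def save_trajectory_csv(traj: Trajectory, path) -> Path:
    """Write activity CSV plus a JSON sidecar with parameters and seed."""
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.8g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(_sidecar(traj), indent=2) + "\n")
    return path


def save_trajectory_hdf5(traj: Trajectory, path) -> Path:
    """HDF5 container with activity, weight series and metadata."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("E", data=traj.E_series)
        fh.create_dataset("I", data=traj.I_series)
        fh.create_dataset("W_times", data=traj.W_times)
        fh.create_dataset("W", data=traj.W_series)
        fh.create_dataset("drive", data=traj.drive_series)
        fh.attrs["metadata"] = json.dumps(_sidecar(traj))
    return path


def write_manifest(path, *, seed: int, params: ModelParams | None = None,
                   settings: RunSettings | None = None, extra: dict | None = None) -> Path:
    """JSON manifest making a persisted result reproducible."""
    from . import __version__

    doc: dict = {"software": "wcplast", "version": __version__, "seed": seed}
    if params is not None:
        doc["model"] = dataclasses.asdict(params)
    if settings is not None:
        doc["run"] = dataclasses.asdict(settings)
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")
    return path


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
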