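"""Configuration files and trajectory containers.

Chain specs are YAML mappings mirroring :class:`ChainSpec`, with the
mechanism-specific keys nested under ``control:``. Trajectories are stored
as HDF5 (groups: config snapshot, times, track coordinates, trap signs,
seed) with a flat-CSV export for interoperability.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .errors import ConfigurationError
from .geometry import ChainSpec, Mechanism, build_chain

__all__ = [
    "spec_to_dict",
    "spec_from_dict",
    "load_spec",
    "dump_spec",
    "save_trajectory",
    "load_trajectory",
    "trajectory_to_csv",
]

_CONTROL_KEYS = ("mechanism", "group_size", "d_x", "a_x", "f_x")


def spec_to_dict(spec: ChainSpec) -> dict:
    d = dataclasses.asdict(spec)
    control = {k: d.pop(k) for k in _CONTROL_KEYS}
    control["mechanism"] = Mechanism(control["mechanism"]).value
    d["control"] = control
    return d


def spec_from_dict(data: dict) -> ChainSpec:
    data = dict(data)
    control = data.pop("control", {})
    unknown = set(data) | set(control)
    fields = {f.name for f in dataclasses.fields(ChainSpec)}
    unknown -= fields
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return ChainSpec(**data, **control)


def load_spec(path: str | Path) -> ChainSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    return spec_from_dict(data)


def dump_spec(spec: ChainSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("config")
        g.attrs["spec_json"] = json.dumps(spec_to_dict(traj.config.spec))
        g.create_dataset("track_centers", data=traj.config.track_centers)
        g.create_dataset("per_rower_amplitude", data=traj.config.per_rower_amplitude)
        g.create_dataset("per_rower_trap_strength", data=traj.config.per_rower_trap_strength)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("track_coords", data=traj.track_coords)
        fh.create_dataset("trap_signs", data=traj.trap_signs)
        fh.attrs["seed"] = -1 if traj.seed is None else traj.seed
        fh.attrs["dt_cycles"] = traj.dt_cycles
        fh.attrs["engine"] = traj.engine


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        spec = spec_from_dict(json.loads(fh["config"].attrs["spec_json"]))
        seed = int(fh.attrs["seed"])
        traj = Trajectory(
            times=fh["times"][...],
            track_coords=fh["track_coords"][...],
            trap_signs=fh["trap_signs"][...].astype(np.int8),
            seed=None if seed < 0 else seed,
            config=build_chain(spec),
            dt_cycles=float(fh.attrs["dt_cycles"]),
            engine=str(fh.attrs["engine"]),
        )
    return traj


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Flat export: one row per (sample, rower)."""
    s, n = traj.track_coords.shape
    a = traj.config.spec.bead_radius
    phases = traj.phases()
    df = pd.DataFrame({
        "time_cycles": np.repeat(traj.times, n),
        "rower_index": np.tile(np.arange(n), s),
        "u_over_a": traj.track_coords.ravel() / a,
        "sigma": traj.trap_signs.ravel(),
        "phase": phases.ravel(),
    })
    df.to_csv(path, index=False)
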