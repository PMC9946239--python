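"""Configs, trace/trajectory files and HDF5 bundles.

Conventions: CSV is comma-separated, UTF-8, "." decimal, one header row.
Column dialects::

    trace CSV       t_ms, I_command_nA, I_injected_nA, V_mV,
                    I_L, I_Kd, I_Ca, I_KCa, Ca_uM, alpha_deg
    clamp CSV       t_ms, I_command_nA, V_read_mV, V_inject_mV
    angle CSV       t_ms, alpha_deg
    trajectory CSV  t_s, x_um, y_um, z_um, gamma_deg, V_mV, Ca_uM,
                    backward_flag

HDF5 bundles carry ``/meta`` (run manifest: config hash, root seed,
package version, per-dataset sha256 checksums) and one group per payload.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .ephys import Trace
from .params import CellParams, ParameterError, preset, PRESET_NAMES

__all__ = ["load_config", "save_config", "write_trace_csv",
           "read_clamp_csv", "write_trajectory_csv", "read_trajectory_csv",
           "RunManifest", "write_bundle", "read_bundle"]


def load_config(path) -> CellParams:
    """Load and validate a cell-parameter config (YAML).

    A top-level ``preset`` key seeds the parameters from a bundled median
    table; explicit sections override individual fields.  Unknown keys and
    invariant violations raise :class:`ParameterError` with the offending
    path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    base = None
    if "preset" in raw:
        name = raw.pop("preset")
        if name not in PRESET_NAMES:
            raise ParameterError(
                f"{path}: unknown preset {name!r}; available {PRESET_NAMES}")
        base = preset(name)
    try:
        if base is None:
            return CellParams.from_dict(raw)
        merged = base.to_dict()
        for section, value in raw.items():
            if isinstance(value, dict):
                merged.setdefault(section, {}).update(value)
            else:
                merged[section] = value
        return CellParams.from_dict(merged)
    except (ParameterError, TypeError) as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def save_config(params: CellParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def write_trace_csv(trace: Trace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_clamp_csv(path):
    """Read a current-clamp sweep (t_ms, I_command_nA, V_read_mV[, V_inject_mV])."""
    df = pd.read_csv(path)
    need = {"t_ms", "I_command_nA", "V_read_mV"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_trajectory_csv(traj, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path, column_map: Optional[Dict[str, str]] = None):
    """Read a trajectory CSV into a :class:`TrackedTrajectory`.

    ``column_map`` renames foreign (tracker-specific) columns onto the
    package dialect, e.g. ``{"imageNumber": "frame", ...}``.
    """
    from .analysis import TrackedTrajectory
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return TrackedTrajectory(
        t=df["t_s"].to_numpy(), x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(), gamma=df["gamma_deg"].to_numpy(),
        eccentricity=df["eccentricity"].to_numpy()
        if "eccentricity" in df.columns else None)


# --------------------------------------------------------------------------
# HDF5 bundle with manifest
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance of one run: config hash, root seed, output checksums."""
    config_hash: str = ""
    seed: int = 0
    version: str = "0.1.0"
    checksums: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "checksums": self.checksums},
            sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunManifest":
        d = json.loads(s)
        return cls(config_hash=d["config_hash"], seed=d["seed"],
                   version=d["version"], checksums=d["checksums"])


def config_hash(params: CellParams) -> str:
    return hashlib.sha256(
        json.dumps(params.to_dict(), sort_keys=True).encode()).hexdigest()


def _array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_bundle(datasets: Dict[str, Dict[str, np.ndarray]], path,
                 params: Optional[CellParams] = None, seed: int = 0) -> None:
    """Write named array groups plus a checksummed manifest to HDF5."""
    manifest = RunManifest(
        config_hash=config_hash(params) if params is not None else "",
        seed=seed)
    with h5py.File(path, "w") as fh:
        for group, arrays in datasets.items():
            g = fh.create_group(group)
            for name, arr in arrays.items():
                arr = np.asarray(arr)
                g.create_dataset(name, data=arr)
                manifest.checksums[f"{group}/{name}"] = _array_checksum(arr)
        fh.attrs["manifest"] = manifest.to_json()


def read_bundle(path) -> Dict[str, Dict[str, np.ndarray]]:
    """Read a bundle back, verifying every dataset checksum."""
    out: Dict[str, Dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as fh:
        manifest = RunManifest.from_json(fh.attrs["manifest"])
        for group in fh:
            out[group] = {}
            for name in fh[group]:
                arr = fh[group][name][()]
                key = f"{group}/{name}"
                want = manifest.checksums.get(key)
                got = _array_checksum(arr)
                if want != got:
                    raise IOError(
                        f"{path}: checksum mismatch for {key} "
                        "(truncated or corrupted bundle)")
                out[group][name] = arr
    return out
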