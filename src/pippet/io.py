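"""File I/O shared by the CLI and experiments: event streams, trajectories,
configs and run manifests.

All CSV floats are written with 9 significant digits so reruns diff
cleanly; comparisons elsewhere use numeric tolerances, never strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .patippet_filter import PatippetConfig, Trajectory2D
from .pippet_filter import EventStream, FilterConfig, FilterTrajectory

__all__ = [
    "read_event_stream",
    "write_event_stream",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

_FLOAT_FMT = "%.9g"

_FILTER_KEYS = {"dt", "sigma", "mu0", "V0", "t_end"}
_PATIPPET_KEYS = {"dt", "sigma", "sigma_theta", "mu2_0", "V2_0", "t_end"}


def read_event_stream(path) -> EventStream:
    """Read a `time[,stream]` CSV into a validated event stream."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing required 'time' column")
    times = df["time"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        raise ValueError(
            f"{path}: event times not strictly increasing at line {bad[0] + 3}"
        )
    labels = None
    if "stream" in df.columns:
        labels = tuple(str(s) for s in df["stream"])
    return EventStream(times=times, labels=labels)


def write_event_stream(stream: EventStream, path) -> None:
    data = {"time": stream.times}
    if stream.labels is not None:
        data["stream"] = list(stream.labels)
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format="%.6f")


def load_config(path) -> Union[FilterConfig, PatippetConfig]:
    """Load a filter config; the presence of ``sigma_theta`` (or a 2D
    prior) selects the phase-and-tempo variant."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    is_2d = bool({"sigma_theta", "mu2_0", "V2_0"} & raw.keys())
    allowed = _PATIPPET_KEYS if is_2d else _FILTER_KEYS
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if is_2d:
        if "mu2_0" in raw:
            raw["mu2_0"] = tuple(float(x) for x in raw["mu2_0"])
        if "V2_0" in raw:
            raw["V2_0"] = tuple(tuple(float(x) for x in row) for row in raw["V2_0"])
        return PatippetConfig(**raw)
    return FilterConfig(**raw)


def _trajectory_frame(traj) -> pd.DataFrame:
    n = traj.times.size
    event = np.zeros(n, dtype=int)
    event[traj.event_marks] = 1
    if isinstance(traj, Trajectory2D):
        return pd.DataFrame(
            {
                "time": traj.times,
                "mu_phi": traj.mu_phi,
                "mu_theta": traj.mu_theta,
                "V_pp": traj.V_pp,
                "V_pt": traj.V_pt,
                "V_tt": traj.V_tt,
                "Lambda": traj.Lambda,
                "event": event,
            }
        )
    return pd.DataFrame(
        {
            "time": traj.times,
            "mu": traj.mu,
            "V": traj.V,
            "Lambda": traj.Lambda,
            "event": event,
        }
    )


def write_trajectory(traj, path) -> None:
    """Write a filter trajectory as CSV (1D or 2D schema by type)."""
    _trajectory_frame(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: not a trajectory CSV (no 'time' column)")
    return df


def write_manifest(path, *, config, seed=None, warnings=(), extra=None) -> None:
    """Write the replay manifest for a CLI run (config echo, seed,
    package version, accumulated warnings)."""
    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    manifest = {
        "version": __version__,
        "config": config,
        "seed": seed,
        "warnings": list(warnings),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
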