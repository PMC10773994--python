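"""Readers and writers for trajectory and kymograph tables.

Plain CSV is the interchange format.  Trajectory files carry optional
``# key = value`` header metadata (root id, geometry, units); angle columns
default to radians and time to hours, with declared degrees/minutes
converted on read.  Kymographs are long-format CSV
(time_h, s_mm, kappa_per_mm, length_mm) with masked cells simply absent
from the file and restored as masked on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Kymograph, TipTrajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_kymograph",
    "write_kymograph",
    "RunConfig",
    "load_run_config",
    "save_run_config",
]

_TIME_ALIASES = ("time_h", "time", "t", "hours", "time_hours", "time_min", "time_minutes")
_TIP_ALIASES = (
    "theta_tip_rad",
    "theta_tip",
    "tip_angle",
    "theta",
    "theta_tip_deg",
    "tip_angle_deg",
)
_GZ0_ALIASES = ("theta_gz0_rad", "theta_gz0", "theta_gz0_deg", "gz0_angle")
_LEN_ALIASES = ("length_mm", "length", "l", "organ_length")


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _pick(columns, aliases, hints, role):
    if hints and role in hints:
        name = hints[role]
        if name not in columns:
            raise ValueError(f"hinted column {name!r} for {role} not in file")
        return name
    lowered = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_trajectory(path, column_map: dict | None = None) -> TipTrajectory:
    """Read a tip-angle trajectory from CSV.

    Column names are matched case-insensitively against common aliases;
    ``column_map`` can pin roles explicitly, e.g.
    ``{"time": "T", "theta_tip": "angle"}``.  Angle units come from a
    ``angle_unit`` metadata line or a ``_deg`` column suffix; time in
    minutes (``time_min`` or ``time_unit = min``) is converted to hours.
    """
    path = Path(path)
    meta = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty or has no data rows") from None
    cols = list(df.columns)
    tcol = _pick(cols, _TIME_ALIASES, column_map, "time")
    acol = _pick(cols, _TIP_ALIASES, column_map, "theta_tip")
    if tcol is None or acol is None:
        raise ValueError(
            f"missing required time/theta_tip columns; file has {cols}"
        )
    times = df[tcol].to_numpy(dtype=float)
    if meta.get("time_unit", "").lower() in ("min", "minute", "minutes") or (
        tcol.lower().startswith("time_min")
    ):
        times = times / 60.0
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicated time stamps in trajectory file")

    in_degrees = meta.get("angle_unit", "").lower() in ("deg", "degree", "degrees")

    def angles(col):
        vals = df[col].to_numpy(dtype=float)
        if in_degrees or col.lower().endswith("_deg"):
            vals = np.radians(vals)
        return vals

    gcol = _pick(cols, _GZ0_ALIASES, column_map, "theta_gz0")
    lcol = _pick(cols, _LEN_ALIASES, column_map, "length")
    return TipTrajectory(
        times_t=times,
        theta_tip=angles(acol),
        theta_gz0=None if gcol is None else angles(gcol),
        length_L=None if lcol is None else df[lcol].to_numpy(dtype=float),
        meta=meta,
    )


def write_trajectory(traj: TipTrajectory, path, meta: dict | None = None) -> None:
    """Write a trajectory as CSV (hours/radians) with ``#`` metadata headers."""
    path = Path(path)
    header = {"time_unit": "h", "angle_unit": "rad"}
    header.update(traj.meta or {})
    header.update(meta or {})
    data = {"time_h": traj.times_t, "theta_tip_rad": traj.theta_tip}
    if traj.theta_gz0 is not None:
        data["theta_gz0_rad"] = traj.theta_gz0
    if traj.length_L is not None:
        data["length_mm"] = traj.length_L
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key} = {value}\n")
        pd.DataFrame(data).to_csv(fh, index=False, lineterminator="\n")


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write a kymograph as long-format CSV; masked cells are omitted."""
    path = Path(path)
    mask = np.ma.getmaskarray(kymo.kappa)
    ti, si = np.nonzero(~mask)
    df = pd.DataFrame(
        {
            "time_h": kymo.t_grid[ti],
            "s_mm": kymo.s_grid[si],
            "kappa_per_mm": np.ma.filled(kymo.kappa, np.nan)[ti, si],
            "length_mm": kymo.length_per_time[ti],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_kymograph(path) -> Kymograph:
    """Read a long-format kymograph CSV back onto its masked grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    required = {"time_h", "s_mm", "kappa_per_mm", "length_mm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"kymograph file must have columns {sorted(required)}, got "
            f"{list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path} has no data rows")
    t_grid = np.unique(df["time_h"].to_numpy(dtype=float))
    s_grid = np.unique(df["s_mm"].to_numpy(dtype=float))
    kappa = np.ma.masked_all((t_grid.size, s_grid.size))
    ti = np.searchsorted(t_grid, df["time_h"].to_numpy(dtype=float))
    si = np.searchsorted(s_grid, df["s_mm"].to_numpy(dtype=float))
    kappa[ti, si] = df["kappa_per_mm"].to_numpy(dtype=float)
    lengths = np.full(t_grid.size, np.nan)
    lengths[ti] = df["length_mm"].to_numpy(dtype=float)
    if np.any(np.isnan(lengths)):
        raise ValueError("inconsistent grid: some times carry no length")
    return Kymograph(
        s_grid=s_grid, t_grid=t_grid, kappa=kappa, length_per_time=lengths
    )


@dataclass
class RunConfig:
    """Serializable run configuration for the command-line interface."""

    model: str = "root"
    eta: float | None = None
    beta: float | None = None
    gamma: float = 1.6
    theta0: float = 0.0
    theta_g: float = float(np.pi / 2)
    radius: float = 0.065
    lgz: float = 0.60
    vg: float = 0.13
    duration: float = 24.0
    dt: float = 1.0 / 6.0
    noise: float = 0.0
    seed: int | None = None
    screen_r2: float = 0.9

    def __post_init__(self):
        if (self.eta is None) == (self.beta is None):
            raise ValueError("exactly one of eta or beta (with geometry) required")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig(**payload)


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def write_json_report(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
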