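"""Readers and writers for the CSV and TIFF dialects the pipeline consumes.

CSV files are comma-separated with a required header row; column names and
units are configurable because rheometer and indenter exports vary.  Torque
units accepted: ``N.m`` (canonical), ``mN.m``, ``uN.m``.  Displacement:
``m``, ``mm``, ``um``; force: ``N``, ``mN``, ``uN``.  Image stacks are plain
multi-page TIFFs, one file per channel or one interleaved two-channel file.

Every preprocessing discard (duplicate ω collapsed, retraction samples
dropped) is logged with counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (
    DiscGeometry,
    FluidProperties,
    ForceDisplacementCurve,
    ImageStack,
    ModulusTable,
    ProbeGeometry,
    TorqueVelocityCurve,
)
from .errors import ConfigError, EmptyInputError, FormatError, TooShortError

log = logging.getLogger(__name__)

__all__ = [
    "TORQUE_UNITS",
    "OMEGA_UNITS",
    "LENGTH_UNITS",
    "FORCE_UNITS",
    "read_rheometry_csv",
    "write_rheometry_csv",
    "read_indentation_csv",
    "write_indentation_csv",
    "read_image_stack",
    "write_image_stack",
    "read_modulus_csv",
    "write_modulus_csv",
    "load_config",
    "geometry_from_config",
    "fluid_from_config",
    "probe_from_config",
]

TORQUE_UNITS = {"N.m": 1.0, "mN.m": 1e-3, "uN.m": 1e-6}
OMEGA_UNITS = {"rad/s": 1.0}
LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6}
FORCE_UNITS = {"N": 1.0, "mN": 1e-3, "uN": 1e-6}


def _unit_factor(unit: str, table: Mapping[str, float], kind: str) -> float:
    try:
        return table[unit]
    except KeyError:
        raise ConfigError(
            f"unknown {kind} unit {unit!r}; accepted: {sorted(table)}"
        ) from None


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if frame.empty:
        raise EmptyInputError(f"{path} has a header but no data rows")
    return frame


def _require_column(frame: pd.DataFrame, name: str, path) -> np.ndarray:
    if name not in frame.columns:
        raise FormatError(f"{path}: required column {name!r} not found "
                          f"(columns present: {list(frame.columns)})")
    return frame[name].to_numpy(dtype=float)


def read_rheometry_csv(
    path,
    geometry: DiscGeometry | None = None,
    fluid: FluidProperties | None = None,
    *,
    omega_col: str = "angular_velocity",
    torque_col: str = "torque",
    time_col: str | None = None,
    omega_unit: str = "rad/s",
    torque_unit: str = "N.m",
    meta: dict | None = None,
) -> TorqueVelocityCurve:
    """Parse one rheometer export into a validated torque-velocity curve.

    Rows are sorted by angular velocity; duplicate ω values are collapsed to
    their mean torque (logged).  ``geometry`` and ``fluid`` are accepted for
    interface symmetry and attached to ``meta`` when given.
    """
    frame = _read_csv(path)
    omega = _require_column(frame, omega_col, path) * _unit_factor(omega_unit, OMEGA_UNITS, "angular-velocity")
    torque = _require_column(frame, torque_col, path) * _unit_factor(torque_unit, TORQUE_UNITS, "torque")
    time = _require_column(frame, time_col, path) if time_col else None

    order = np.argsort(omega, kind="stable")
    omega, torque = omega[order], torque[order]
    if time is not None:
        time = time[order]

    uniq, inverse, counts = np.unique(omega, return_inverse=True, return_counts=True)
    if uniq.size < omega.size:
        n_dup = int(omega.size - uniq.size)
        mean_t = np.zeros_like(uniq)
        np.add.at(mean_t, inverse, torque)
        mean_t /= counts
        if time is not None:
            mean_time = np.zeros_like(uniq)
            np.add.at(mean_time, inverse, time)
            time = mean_time / counts
        log.warning("%s: collapsed %d duplicate angular-velocity rows by mean", path, n_dup)
        omega, torque = uniq, mean_t

    meta = dict(meta or {})
    if geometry is not None:
        meta.setdefault("geometry", geometry)
    if fluid is not None:
        meta.setdefault("fluid", fluid)
    return TorqueVelocityCurve(omega=omega, torque=torque, time=time, meta=meta)


def write_rheometry_csv(curve: TorqueVelocityCurve, path) -> None:
    cols = {"angular_velocity": curve.omega, "torque": curve.torque}
    if curve.time is not None:
        cols["time"] = curve.time
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_indentation_csv(
    path,
    *,
    displacement_col: str = "displacement",
    force_col: str = "force",
    displacement_unit: str = "m",
    force_unit: str = "N",
    min_samples: int = 10,
    meta: dict | None = None,
) -> ForceDisplacementCurve:
    """Parse one indentation export, keeping only the approach segment.

    Samples after the global displacement maximum (retraction) are discarded
    with a logged warning; the approach is then made monotone by a stable
    sort on displacement.
    """
    frame = _read_csv(path)
    disp = _require_column(frame, displacement_col, path) * _unit_factor(
        displacement_unit, LENGTH_UNITS, "displacement")
    force = _require_column(frame, force_col, path) * _unit_factor(force_unit, FORCE_UNITS, "force")

    imax = int(np.argmax(disp))
    if imax < disp.size - 1:
        n_drop = disp.size - 1 - imax
        log.warning("%s: discarded %d retraction samples after displacement maximum", path, n_drop)
        disp, force = disp[: imax + 1], force[: imax + 1]

    order = np.argsort(disp, kind="stable")
    disp, force = disp[order], force[order]

    if disp.size < min_samples:
        raise TooShortError(f"{path}: only {disp.size} approach samples (need >= {min_samples})")
    if disp[-1] - disp[0] <= 0:
        raise FormatError(f"{path}: non-positive displacement span")
    return ForceDisplacementCurve(displacement=disp, force=force, meta=dict(meta or {}))


def write_indentation_csv(curve: ForceDisplacementCurve, path) -> None:
    pd.DataFrame({"displacement": curve.displacement, "force": curve.force}).to_csv(
        path, index=False, float_format="%.17g")


def read_image_stack(
    path,
    voxel_size: Sequence[float] | None = None,
    channel_map: Mapping[int, str] | None = None,
    *,
    top_down: bool = False,
) -> ImageStack:
    """Load a confocal stack from TIFF.

    Two layouts are supported:

    * ``path`` is a mapping ``{role: tiff_path}`` of single-channel stacks;
    * ``path`` is one interleaved file whose pages cycle through channels in
      z-major order, with ``channel_map`` mapping page phase to role,
      e.g. ``{0: "cells", 1: "eps"}``.

    ``voxel_size`` is (dz, dy, dx) in µm and is required.  With
    ``top_down=True`` the z axis is reversed so slice 0 is the substratum.
    """
    if voxel_size is None:
        raise ConfigError("voxel_size (dz, dy, dx) in µm is required to read a stack")
    if isinstance(path, Mapping):
        channels = {role: tifffile.imread(p) for role, p in path.items()}
    else:
        pages = tifffile.imread(path)
        if channel_map is None:
            channel_map = {0: "channel0"}
        nch = len(channel_map)
        if pages.shape[0] % nch:
            raise FormatError(
                f"{path}: {pages.shape[0]} pages not divisible by {nch} channels")
        channels = {role: pages[phase::nch] for phase, role in channel_map.items()}
    shapes = {v.shape for v in channels.values()}
    if len(shapes) != 1:
        raise FormatError(f"channel shape mismatch: {shapes}")
    if top_down:
        channels = {k: v[::-1] for k, v in channels.items()}
    return ImageStack(channels=channels, voxel_size=tuple(voxel_size))


def write_image_stack(stack: ImageStack, paths: Mapping[str, object]) -> None:
    """Write one single-channel TIFF per role; boolean channels as uint8 0/1."""
    for role, p in paths.items():
        arr = np.asarray(stack.channels[role])
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        tifffile.imwrite(p, arr)


def read_modulus_csv(path) -> ModulusTable:
    frame = _read_csv(path)
    for col in ("group", "replicate", "modulus_pa"):
        if col not in frame.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    return ModulusTable.from_frame(frame)


def write_modulus_csv(table: ModulusTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return cfg


def geometry_from_config(cfg: Mapping) -> DiscGeometry:
    sub = cfg.get("geometry", {})
    return DiscGeometry(radius=sub.get("radius", 0.020), gap=sub.get("gap", 0.035))


def fluid_from_config(cfg: Mapping) -> FluidProperties:
    sub = cfg.get("fluid", {})
    return FluidProperties(
        density=sub.get("density", 998.0),
        kinematic_viscosity=sub.get("kinematic_viscosity", 1.0e-6),
    )


def probe_from_config(cfg: Mapping) -> ProbeGeometry:
    sub = cfg.get("probe", {})
    return ProbeGeometry(
        radius=sub.get("radius", 0.004), poisson_ratio=sub.get("poisson_ratio", 0.5)
    )
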