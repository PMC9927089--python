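"""Shared domain types.

Every quantity is held internally in canonical SI units (m, N, N·m, rad/s,
Pa); conversion to display units happens only at reporting time.  Image-stack
voxel sizes are the one exception: they are carried in µm because biomass and
column heights are conventionally reported in µm³/µm² and µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, FormatError, TooShortError

__all__ = [
    "DiscGeometry",
    "FluidProperties",
    "ProbeGeometry",
    "TorqueVelocityCurve",
    "ForceDisplacementCurve",
    "ImageStack",
    "ModulusTable",
]


@dataclass(frozen=True)
class DiscGeometry:
    """Rotating-disc coupon geometry.

    Parameters
    ----------
    radius : float
        Coupon radius in m (default 0.020, a 40 mm diameter coupon).
    gap : float
        Distance between coupon and container floor in m (default 0.035).
    """

    radius: float = 0.020
    gap: float = 0.035

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.gap <= 0:
            raise DomainError("disc radius and gap must be positive")


@dataclass(frozen=True)
class FluidProperties:
    """Immersion-fluid properties; defaults are water at 20 °C."""

    density: float = 998.0          # kg/m^3
    kinematic_viscosity: float = 1.0e-6  # m^2/s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise DomainError("fluid density and viscosity must be positive")


@dataclass(frozen=True)
class ProbeGeometry:
    """Flat cylindrical indentation probe.

    ``radius`` in m (default 0.004, an 8 mm probe); ``poisson_ratio`` is the
    assumed Poisson's ratio of the biofilm, 0.5 = incompressible.
    """

    radius: float = 0.004
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DomainError("probe radius must be positive")
        if not 0.0 <= self.poisson_ratio < 1.0:
            raise DomainError("Poisson ratio must lie in [0, 1)")

    @property
    def contact_area(self) -> float:
        """Full flat-probe contact area π r² in m²."""
        return float(np.pi * self.radius**2)


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TorqueVelocityCurve:
    """One rotating-disc run: resistive torque sampled along a velocity ramp.

    ``omega`` (rad/s) must be strictly increasing; ``torque`` (N·m) finite;
    ``time`` (s) is optional instrument time.  ``meta`` carries coupon id and
    treatment label.
    """

    omega: np.ndarray
    torque: np.ndarray
    time: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = _as_1d_float(self.omega, "omega")
        self.torque = _as_1d_float(self.torque, "torque")
        if self.omega.size != self.torque.size:
            raise FormatError("omega and torque must have the same length")
        if self.omega.size < 3:
            raise TooShortError("torque-velocity curve needs at least 3 samples")
        if not np.all(np.diff(self.omega) > 0):
            raise FormatError("omega must be strictly increasing")
        if not np.all(np.isfinite(self.torque)) or not np.all(np.isfinite(self.omega)):
            raise FormatError("omega and torque must be finite")
        if self.time is not None:
            self.time = _as_1d_float(self.time, "time")
            if self.time.size != self.omega.size:
                raise FormatError("time must match omega length")

    def __len__(self) -> int:
        return int(self.omega.size)


@dataclass
class ForceDisplacementCurve:
    """One indentation approach: normal force vs probe displacement.

    ``displacement`` (m, increasing toward the substratum) must be monotone
    non-decreasing; ``force`` in N.
    """

    displacement: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = _as_1d_float(self.displacement, "displacement")
        self.force = _as_1d_float(self.force, "force")
        if self.displacement.size != self.force.size:
            raise FormatError("displacement and force must have the same length")
        if self.displacement.size < 2:
            raise TooShortError("force-displacement curve needs at least 2 samples")
        if np.any(np.diff(self.displacement) < 0):
            raise FormatError("displacement must be monotone non-decreasing")
        if not np.all(np.isfinite(self.force)):
            raise FormatError("force must be finite")

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass
class ImageStack:
    """Multi-channel 3-D voxel grid.

    ``channels`` maps a role name (conventionally ``"cells"`` and ``"eps"``)
    to a (nz, ny, nx) array; slice z=0 is the substratum plane.
    ``voxel_size`` is (dz, dy, dx) in µm.
    """

    channels: Mapping[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.channels = dict(self.channels)
        if not self.channels:
            raise FormatError("stack must have at least one channel")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise FormatError(f"channels must share one shape, got {shapes}")
        shape = shapes.pop()
        if len(shape) != 3:
            raise FormatError("channel arrays must be 3-D (z, y, x)")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise FormatError("voxel_size must be three positive numbers (dz, dy, dx) in µm")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height_um(self) -> float:
        """Physical stack height nz·dz in µm."""
        return self.shape[0] * self.voxel_size[0]


@dataclass
class ModulusTable:
    """Per-replicate Young's moduli keyed by treatment group.

    Thin wrapper over a records list; use :meth:`to_frame` for a tidy
    DataFrame (columns group, replicate, modulus_pa).
    """

    records: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, group: str, replicate: str, modulus_pa: float) -> None:
        if not np.isfinite(modulus_pa) or modulus_pa <= 0:
            raise DomainError(f"Young's modulus must be positive and finite, got {modulus_pa}")
        self.records.append((str(group), str(replicate), float(modulus_pa)))

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _, _ in self.records:
            seen.setdefault(g, None)
        return list(seen)

    def moduli(self, group: str) -> np.ndarray:
        """Moduli of one group, ordered by replicate id (stable sort)."""
        recs = sorted(
            ((r, e) for g, r, e in self.records if g == group), key=lambda t: t[0]
        )
        return np.array([e for _, e in recs], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["group", "replicate", "modulus_pa"])

    @classmethod
    def from_frame(cls, frame) -> "ModulusTable":
        table = cls()
        for _, row in frame.iterrows():
            table.add(row["group"], row["replicate"], row["modulus_pa"])
        return table

    def __len__(self) -> int:
        return len(self.records)
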