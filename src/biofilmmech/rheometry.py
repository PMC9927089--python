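"""Rotating-disc rheometry detachment analysis.

A biofilm-coated coupon is spun through an angular-velocity ramp while the
resistive torque is recorded.  Four quantities summarise one run:

* the **biofilm momentum coefficient** Cf — mean excess of the measured
  moment coefficient Cm = T / (½ρω²R⁵) over the theoretical one-sided
  smooth-disc coefficient, averaged over the top velocity decade; a
  dimensionless measure of biofilm-induced drag;
* the **AUC** — trapezoidal area under the torque-velocity curve, an index
  of the energy needed to spin the coupon across the ramp;
* **detachment events** — step drops in torque, revealed by subtracting the
  full-run least-squares line and differencing (an approximation of the
  first derivative), then flagging strongly negative slopes with a robust
  median/MAD rule;
* the **critical detachment shear stress** τ* — the laminar disc-edge wall
  shear stress at the lowest-velocity event, i.e. the stress at which the
  biofilm first begins to shed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import DiscGeometry, FluidProperties, TorqueVelocityCurve
from .errors import DomainError, TooShortError

__all__ = [
    "SlopeSeries",
    "DetachmentEvent",
    "RheometryMetrics",
    "smooth_disc_moment_coefficient",
    "momentum_coefficient_curve",
    "biofilm_momentum_coefficient",
    "linearized_slope_transform",
    "detect_detachment_events",
    "wall_shear_stress",
    "critical_detachment_shear_stress",
    "torque_auc",
    "analyze_torque_curve",
]

#: Reynolds number at the laminar/turbulent branch switch for a rotating disc.
RE_TRANSITION = 3.0e5

#: Disc-edge laminar wall-shear coefficient, sqrt(0.616² + 0.510²) rounded.
WALL_SHEAR_COEFF = 0.800

#: Default averaging window for the biofilm momentum coefficient: the top
#: decade of the 0.1-300 rad/s ramp.
DEFAULT_CF_WINDOW = (30.0, 300.0)


@dataclass
class SlopeSeries:
    """First-difference slope of baseline-corrected torque vs ω."""

    omega_mid: np.ndarray   # rad/s, midpoints between consecutive samples
    slope: np.ndarray       # N·m per rad/s


@dataclass(frozen=True)
class DetachmentEvent:
    """One detected step reduction in torque."""

    omega: float         # rad/s at the most negative slope of the run
    slope: float         # N·m/(rad/s), negative
    shear_stress: float  # Pa, wall shear at this omega


@dataclass
class RheometryMetrics:
    """Per-coupon summary of one torque-velocity run."""

    momentum_coefficient: float
    auc: float
    critical_shear_stress: float | None
    events: list[DetachmentEvent] = field(default_factory=list)


def smooth_disc_moment_coefficient(
    omega, geometry: DiscGeometry = DiscGeometry(), fluid: FluidProperties = FluidProperties()
):
    """One-sided moment coefficient of a clean rotating disc.

    Von Kármán similarity results for one wetted face:
    laminar ``1.935·Re^(-1/2)`` for Re ≤ 3×10⁵ (boundary inclusive),
    turbulent ``0.0365·Re^(-1/5)`` above, with Re = ωR²/ν.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise DomainError("angular velocity must be positive")
    re = omega * geometry.radius**2 / fluid.kinematic_viscosity
    cm = np.where(re <= RE_TRANSITION, 1.935 * re**-0.5, 0.0365 * re**-0.2)
    return cm if cm.ndim else float(cm)


def momentum_coefficient_curve(
    curve: TorqueVelocityCurve,
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> np.ndarray:
    """Measured moment coefficient Cm(ω) = T / (½ ρ ω² R⁵) per sample."""
    if np.any(curve.omega <= 0):
        raise DomainError("angular velocity must be positive to form Cm")
    return curve.torque / (0.5 * fluid.density * curve.omega**2 * geometry.radius**5)


def biofilm_momentum_coefficient(
    curve: TorqueVelocityCurve,
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
    window: tuple[float, float] = DEFAULT_CF_WINDOW,
) -> float:
    """Mean excess drag coefficient Cf over the smooth-disc baseline.

    Averages ``Cm(ω) − Cm_smooth(Re)`` over samples with ω inside ``window``
    (inclusive).  The default window is the top decade of the ramp, where
    biofilm drag dominates instrument noise.
    """
    lo, hi = window
    mask = (curve.omega >= lo) & (curve.omega <= hi)
    if not np.any(mask):
        raise DomainError(f"no samples inside the averaging window {window}")
    cm = momentum_coefficient_curve(curve, geometry, fluid)
    cm_s = smooth_disc_moment_coefficient(curve.omega, geometry, fluid)
    return float(np.mean((cm - cm_s)[mask]))


def linearized_slope_transform(curve: TorqueVelocityCurve) -> SlopeSeries:
    """Baseline-correct the torque curve and difference it.

    The least-squares line fitted to (ω, T) over the full run is subtracted
    (baseline correction), then the corrected torque is differenced between
    consecutive samples and divided by Δω.  Step reductions in torque appear
    as strongly negative slope values.
    """
    if len(curve) < 3:
        raise TooShortError("slope transform needs at least 3 samples")
    omega, torque = curve.omega, curve.torque
    if np.ptp(omega) == 0:
        raise DomainError("degenerate curve: all angular velocities equal")
    b, a = np.polyfit(omega, torque, 1)
    corrected = torque - (a + b * omega)
    slope = np.diff(corrected) / np.diff(omega)
    omega_mid = 0.5 * (omega[:-1] + omega[1:])
    return SlopeSeries(omega_mid=omega_mid, slope=slope)


def detect_detachment_events(
    slopes: SlopeSeries,
    threshold_sd: float = 3.0,
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> list[DetachmentEvent]:
    """Flag slope values below ``median − threshold_sd × robust SD``.

    The robust SD is 1.4826×MAD of the slope series.  Consecutive flagged
    midpoints are merged into a single event located at the most negative
    slope.  Returns an empty list when nothing is flagged.
    """
    if threshold_sd <= 0:
        raise DomainError("threshold_sd must be positive")
    s = slopes.slope
    med = float(np.median(s))
    robust_sd = 1.4826 * float(np.median(np.abs(s - med)))
    threshold = med - threshold_sd * robust_sd
    flagged = s < threshold

    events: list[DetachmentEvent] = []
    i = 0
    n = s.size
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            k = i + int(np.argmin(s[seg]))
            om = float(slopes.omega_mid[k])
            events.append(
                DetachmentEvent(
                    omega=om,
                    slope=float(s[k]),
                    shear_stress=wall_shear_stress(om, geometry, fluid),
                )
            )
            i = j + 1
        else:
            i += 1
    return events


def wall_shear_stress(
    omega, geometry: DiscGeometry = DiscGeometry(), fluid: FluidProperties = FluidProperties()
):
    """Laminar rotating-disc wall shear magnitude at the coupon edge.

    τ = 0.800 · ρ · R · sqrt(ν ω³); valid through the whole 0.1-300 rad/s
    ramp, which stays laminar (Re ≤ 1.2×10⁵) for a 40 mm coupon in water.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise DomainError("angular velocity must be non-negative")
    tau = (
        WALL_SHEAR_COEFF
        * fluid.density
        * geometry.radius
        * np.sqrt(fluid.kinematic_viscosity * omega**3)
    )
    return tau if tau.ndim else float(tau)


def critical_detachment_shear_stress(
    curve: TorqueVelocityCurve,
    events: list[DetachmentEvent],
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
) -> float | None:
    """Wall shear stress at the lowest-velocity detachment event.

    Returns ``None`` (missing, not zero) when no events were detected.
    """
    if not events:
        return None
    om = min(e.omega for e in events)
    return float(wall_shear_stress(om, geometry, fluid))


def torque_auc(curve: TorqueVelocityCurve) -> float:
    """Trapezoidal integral of torque over the recorded ω range (N·m·rad/s)."""
    return float(np.trapezoid(curve.torque, curve.omega))


def analyze_torque_curve(
    curve: TorqueVelocityCurve,
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
    window: tuple[float, float] = DEFAULT_CF_WINDOW,
    threshold_sd: float = 3.0,
) -> RheometryMetrics:
    """Full per-coupon analysis: Cf, AUC, events and τ*."""
    slopes = linearized_slope_transform(curve)
    events = detect_detachment_events(slopes, threshold_sd, geometry, fluid)
    return RheometryMetrics(
        momentum_coefficient=biofilm_momentum_coefficient(curve, geometry, fluid, window),
        auc=torque_auc(curve),
        critical_shear_stress=critical_detachment_shear_stress(curve, events, geometry, fluid),
        events=events,
    )
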