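"""Uniaxial flat-probe indentation analysis.

An 8 mm flat probe approaches the biofilm at constant speed while normal
force is recorded.  The analysis finds the contact point (sustained force
rise above the pre-contact baseline), the substratum (abrupt stiffening of
the local force-displacement slope), hence the biofilm thickness
h = δ_s − δ_c; converts force-displacement to engineering stress-strain; and
estimates the Young's modulus from the force-displacement slope restricted
to 0-20% strain:

    E = slope · (1 − v²) / (2 r)

with probe radius r and assumed biofilm Poisson ratio v = 0.5
(incompressible).  The slope is fitted on force vs displacement (N/m)
because that is what the modulus relation consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ForceDisplacementCurve, ProbeGeometry
from .errors import ContactNotFoundError, DomainError, WindowTooSmallError

log = logging.getLogger(__name__)

__all__ = [
    "ContactResult",
    "StressStrainCurve",
    "SlopeFit",
    "ModulusResult",
    "detect_contact_point",
    "detect_substratum",
    "stress_strain",
    "linear_region_slope",
    "youngs_modulus",
    "analyze_indentation_curve",
]


@dataclass(frozen=True)
class ContactResult:
    """Contact and substratum displacements with derived thickness (m)."""

    delta_contact: float
    delta_substratum: float

    def __post_init__(self) -> None:
        if self.delta_substratum <= self.delta_contact:
            raise DomainError("substratum displacement must exceed contact displacement")

    @property
    def thickness(self) -> float:
        return self.delta_substratum - self.delta_contact


@dataclass
class StressStrainCurve:
    """Engineering strain (compression depth / thickness) vs stress (Pa)."""

    strain: np.ndarray
    stress: np.ndarray


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares force-displacement slope with diagnostics."""

    slope: float          # N/m
    intercept: float      # N
    r_squared: float
    index_range: tuple[int, int]  # [first, last] sample index of the window
    n_samples: int


@dataclass(frozen=True)
class ModulusResult:
    """Slope-window fit and the Young's modulus it implies."""

    fit: SlopeFit
    modulus_pa: float
    contact: ContactResult


def detect_contact_point(
    curve: ForceDisplacementCurve,
    k_sd: float = 5.0,
    m_run: int = 10,
    baseline_fraction: float = 0.10,
) -> float:
    """Displacement at which force starts to rise steadily above baseline.

    The pre-contact baseline (mean, SD) is estimated from the first
    ``baseline_fraction`` of samples.  Contact is the first sample whose
    force exceeds ``mean + k_sd·SD`` and stays above for ``m_run``
    consecutive samples.
    """
    if k_sd <= 0 or m_run < 1:
        raise DomainError("k_sd must be positive and m_run >= 1")
    force = curve.force
    n = force.size
    nb = max(int(round(baseline_fraction * n)), 2)
    baseline = force[:nb]
    threshold = float(np.mean(baseline)) + k_sd * float(np.std(baseline))

    above = force > threshold
    # first index i with m_run consecutive True starting at i
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run >= m_run:
            start = i - m_run + 1
            return float(curve.displacement[start])
    raise ContactNotFoundError(
        f"no run of {m_run} samples above baseline + {k_sd} SD "
        f"(threshold {threshold:.3g} N)")


def _local_slopes(disp: np.ndarray, force: np.ndarray, window: int) -> np.ndarray:
    """Centered windowed least-squares slope at each interior sample."""
    half = window // 2
    n = disp.size
    slopes = np.full(n, np.nan)
    if n < window:
        return slopes
    disp = disp - disp.mean()  # conditioning; slope is shift-invariant
    ones = np.ones(window)
    sx = np.convolve(disp, ones, mode="valid")
    sy = np.convolve(force, ones, mode="valid")
    sxy = np.convolve(disp * force, ones, mode="valid")
    sxx = np.convolve(disp * disp, ones, mode="valid")
    denom = window * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (window * sxy - sx * sy) / denom
    vals[denom <= 0] = np.nan
    slopes[half : n - half] = vals
    return slopes


def detect_substratum(
    curve: ForceDisplacementCurve,
    delta_contact: float,
    stiffening_factor: float = 20.0,
    window: int = 11,
) -> float:
    """Displacement where the local slope first stiffens sharply.

    Local slopes are windowed least-squares fits (``window`` samples).  The
    reference slope is the first full post-contact window; the substratum is
    the first sample whose local slope is at least ``stiffening_factor``
    times the reference.  If stiffening is never reached the curve ends at
    the termination load and the last sample is used (logged fallback).
    """
    if stiffening_factor <= 1:
        raise DomainError("stiffening_factor must exceed 1")
    disp, force = curve.displacement, curve.force
    i0 = int(np.searchsorted(disp, delta_contact, side="left"))
    slopes = _local_slopes(disp, force, window)
    half = window // 2

    ref_idx = min(i0 + half, disp.size - half - 1)
    ref = slopes[ref_idx]
    if np.isfinite(ref) and ref > 0:
        candidates = np.arange(ref_idx + 1, disp.size - half)
        for c in candidates:
            if np.isfinite(slopes[c]) and slopes[c] >= stiffening_factor * ref:
                return float(disp[c])
    log.warning(
        "no %sx stiffening found after contact; falling back to the final "
        "(termination-load) sample", stiffening_factor)
    return float(disp[-1])


def stress_strain(
    curve: ForceDisplacementCurve,
    contact: ContactResult,
    probe: ProbeGeometry = ProbeGeometry(),
) -> StressStrainCurve:
    """Convert the biofilm-compression segment to stress vs strain.

    Strain is (δ − δ_c)/h for δ in [δ_c, δ_s]; stress is force over the full
    flat-probe area πr² (the probe is far wider than the film, so full
    contact is assumed).
    """
    h = contact.thickness
    if h <= 0:
        raise DomainError("non-positive biofilm thickness")
    mask = (curve.displacement >= contact.delta_contact) & (
        curve.displacement <= contact.delta_substratum)
    strain = (curve.displacement[mask] - contact.delta_contact) / h
    stress = curve.force[mask] / probe.contact_area
    return StressStrainCurve(strain=strain, stress=stress)


def linear_region_slope(
    curve: ForceDisplacementCurve,
    contact: ContactResult,
    strain_max: float = 0.20,
    min_samples: int = 5,
) -> SlopeFit:
    """Least-squares force-displacement slope over the 0-``strain_max`` strain window."""
    if strain_max <= 0:
        raise WindowTooSmallError("strain_max must be positive")
    h = contact.thickness
    lo = contact.delta_contact
    hi = contact.delta_contact + strain_max * h
    mask = (curve.displacement >= lo) & (curve.displacement <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < min_samples:
        raise WindowTooSmallError(
            f"only {idx.size} samples in the 0-{strain_max:.0%} strain window "
            f"(need >= {min_samples})")
    x = curve.displacement[idx]
    y = curve.force[idx]
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        index_range=(int(idx[0]), int(idx[-1])),
        n_samples=int(idx.size),
    )


def youngs_modulus(slope: float, probe: ProbeGeometry = ProbeGeometry()) -> float:
    """Young's modulus from the force-displacement slope: E = slope(1−v²)/(2r)."""
    if not np.isfinite(slope):
        raise DomainError("slope must be finite")
    return slope * (1.0 - probe.poisson_ratio**2) / (2.0 * probe.radius)


def analyze_indentation_curve(
    curve: ForceDisplacementCurve,
    probe: ProbeGeometry = ProbeGeometry(),
    k_sd: float = 5.0,
    m_run: int = 10,
    stiffening_factor: float = 20.0,
    strain_max: float = 0.20,
) -> ModulusResult:
    """Full per-curve analysis: contact, thickness, slope fit, modulus."""
    delta_c = detect_contact_point(curve, k_sd=k_sd, m_run=m_run)
    delta_s = detect_substratum(curve, delta_c, stiffening_factor=stiffening_factor)
    contact = ContactResult(delta_contact=delta_c, delta_substratum=delta_s)
    fit = linear_region_slope(curve, contact, strain_max=strain_max)
    return ModulusResult(fit=fit, modulus_pa=youngs_modulus(fit.slope, probe), contact=contact)
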