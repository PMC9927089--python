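"""Synthetic instrument data with known ground truth.

Everything the analysis consumes can be generated here: torque-velocity
ramps with step-drop detachment events, flat-probe indentation curves with
pre-contact baseline and substratum stiffening, two-channel boolean (or
8-bit) confocal stacks, and whole four-group treatment studies whose group
parameters default to the reported means/SDs for untreated, arginine-,
zinc-, and DZA-treated biofilms.

Every generator takes a ``seed`` (or an existing ``numpy`` Generator) and is
bit-reproducible; alongside each object it returns a ``truth`` dict holding
every injected parameter so analyses can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DiscGeometry,
    FluidProperties,
    ForceDisplacementCurve,
    ImageStack,
    ProbeGeometry,
    TorqueVelocityCurve,
)
from .errors import DomainError
from .io import write_image_stack, write_indentation_csv, write_rheometry_csv
from .rheometry import smooth_disc_moment_coefficient

__all__ = [
    "GroupSpec",
    "StudySpec",
    "StudyData",
    "default_study_spec",
    "generate_torque_curve",
    "generate_indentation_curve",
    "generate_image_stack",
    "generate_study",
]

RAMP_RANGE = (0.1, 300.0)   # rad/s, instrument ramp limits
RAMP_DURATION_S = 360.0
TERMINATION_FORCE_N = 15.0
E_TRUNCATION_KPA = 0.5      # lower truncation of group modulus draws


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def generate_torque_curve(
    cf0: float,
    events: tuple[tuple[float, float], ...] = (),
    noise_sd: float = 0.0,
    geometry: DiscGeometry = DiscGeometry(),
    fluid: FluidProperties = FluidProperties(),
    n_points: int = 72,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TorqueVelocityCurve, dict]:
    """Simulate one rotating-disc run.

    ω is log-spaced over the 0.1-300 rad/s ramp.  Torque is
    ``½ρω²R⁵·(Cm_smooth(Re) + Cf(ω))·(1 + ε)`` with multiplicative noise
    ε ~ N(0, noise_sd).  ``events`` is a list of (ω_event, fractional_drop)
    pairs: at each event the biofilm drag Cf drops by that fraction and
    stays down (piecewise-constant), emulating aggregate detachment.
    """
    if cf0 < 0:
        raise DomainError("Cf0 must be non-negative")
    lo, hi = RAMP_RANGE
    for om_e, drop in events:
        if not lo < om_e < hi:
            raise DomainError(f"event omega {om_e} outside the ramp ({lo}, {hi})")
        if not 0 < drop <= 1:
            raise DomainError(f"event drop must be in (0, 1], got {drop}")
    gen = _rng(seed, rng)
    omega = np.logspace(np.log10(lo), np.log10(hi), n_points)
    cf = np.full(n_points, float(cf0))
    for om_e, drop in sorted(events):
        cf[omega >= om_e] *= 1.0 - drop
    cm_s = smooth_disc_moment_coefficient(omega, geometry, fluid)
    torque = 0.5 * fluid.density * omega**2 * geometry.radius**5 * (cm_s + cf)
    if noise_sd > 0:
        torque = torque * (1.0 + gen.normal(0.0, noise_sd, n_points))
    time = np.linspace(0.0, RAMP_DURATION_S, n_points)
    curve = TorqueVelocityCurve(omega=omega, torque=torque, time=time)
    truth = {
        "cf0": float(cf0),
        "events": [[float(o), float(d)] for o, d in events],
        "noise_sd": float(noise_sd),
        "n_points": int(n_points),
        "cf_per_point": cf.tolist(),
    }
    return curve, truth


def generate_indentation_curve(
    modulus_pa: float,
    thickness_m: float = 200e-6,
    delta_contact_m: float = 50e-6,
    substratum_ratio: float = 50.0,
    noise_sd: float = 0.0,
    probe: ProbeGeometry = ProbeGeometry(),
    n_points: int = 800,
    overtravel_fraction: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ForceDisplacementCurve, dict]:
    """Simulate one flat-probe indentation approach.

    Force is zero (plus baseline noise) before contact, rises linearly with
    stiffness ``k = 2rE/(1−v²)`` through the biofilm, then stiffens by
    ``substratum_ratio`` beyond the substratum; the run ends at the 15 N
    termination load or after ``overtravel_fraction·h`` of substratum
    travel, whichever comes first.  Noise is additive on force with SD equal
    to ``noise_sd`` times the force at 20% strain (instrument-like).
    """
    if modulus_pa <= 0 or thickness_m <= 0:
        raise DomainError("modulus and thickness must be positive")
    if substratum_ratio <= 1:
        raise DomainError("substratum_ratio must exceed 1")
    gen = _rng(seed, rng)
    k = 2.0 * probe.radius * modulus_pa / (1.0 - probe.poisson_ratio**2)
    span = delta_contact_m + thickness_m * (1.0 + overtravel_fraction)
    disp = np.linspace(0.0, span, n_points)
    delta_s = delta_contact_m + thickness_m
    force = np.where(
        disp < delta_contact_m,
        0.0,
        np.where(
            disp < delta_s,
            k * (disp - delta_contact_m),
            k * thickness_m + substratum_ratio * k * (disp - delta_s),
        ),
    )
    sd_abs = noise_sd * k * 0.2 * thickness_m
    if noise_sd > 0:
        force = force + gen.normal(0.0, sd_abs, n_points)
    over = np.flatnonzero(force > TERMINATION_FORCE_N)
    if over.size:
        stop = over[0] + 1
        disp, force = disp[:stop], force[:stop]
    curve = ForceDisplacementCurve(displacement=disp, force=force)
    truth = {
        "modulus_pa": float(modulus_pa),
        "thickness_m": float(thickness_m),
        "delta_contact_m": float(delta_contact_m),
        "stiffness_n_per_m": float(k),
        "substratum_ratio": float(substratum_ratio),
        "noise_sd": float(noise_sd),
        "force_noise_sd_n": float(sd_abs),
    }
    return curve, truth


def generate_image_stack(
    shape: tuple[int, int, int] = (40, 64, 64),
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5),
    height_distribution: tuple[float, float] = (np.log(20.0), 0.2),
    eps_style: str = "layer",
    eps_coverage: float = 0.3,
    eps_volume_per_area: float = 10.0,
    intensity: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, dict]:
    """Simulate a two-channel biofilm stack (channels ``cells`` and ``eps``).

    Cells: per-column heights drawn lognormal(µ, σ) in µm and filled from
    the substratum.  EPS: either a uniform ``layer`` of thickness
    ``eps_volume_per_area`` µm (volume per area), or ``punctate`` blobs —
    a random ``eps_coverage`` fraction of columns carrying lognormal column
    heights whose expectation matches the same volume per area.

    With ``intensity=True`` channels are 8-bit with two noisy intensity
    levels (background ≈ 20, foreground ≈ 200) for threshold testing;
    otherwise channels are boolean.
    """
    if not 0 < eps_coverage <= 1:
        raise DomainError("eps_coverage must be in (0, 1]")
    gen = _rng(seed, rng)
    nz, ny, nx = shape
    dz = voxel_size[0]
    mu, sigma = height_distribution

    heights_um = gen.lognormal(mu, sigma, size=(ny, nx))
    cells_vox = np.clip(np.round(heights_um / dz).astype(int), 0, nz)
    zidx = np.arange(nz)[:, None, None]
    cells = zidx < cells_vox[None, :, :]

    if eps_style == "layer":
        n_layers = int(round(eps_volume_per_area / dz))
        eps_vox = np.full((ny, nx), min(n_layers, nz), dtype=int)
    elif eps_style == "punctate":
        n_cols = max(int(round(eps_coverage * ny * nx)), 1)
        chosen = gen.choice(ny * nx, size=n_cols, replace=False)
        target_mean = eps_volume_per_area / eps_coverage  # µm per occupied column
        sig = 0.3
        blob_heights = gen.lognormal(np.log(target_mean) - sig**2 / 2, sig, n_cols)
        eps_vox = np.zeros((ny, nx), dtype=int)
        eps_vox.ravel()[chosen] = np.clip(np.round(blob_heights / dz).astype(int), 1, nz)
    else:
        raise DomainError(f"unknown eps_style {eps_style!r}")
    eps = zidx < eps_vox[None, :, :]

    channels: dict[str, np.ndarray] = {"cells": cells, "eps": eps}
    if intensity:
        channels = {
            role: np.clip(
                np.where(arr, 200.0, 20.0) + gen.normal(0.0, 5.0, arr.shape), 0, 255
            ).astype(np.uint8)
            for role, arr in channels.items()
        }
    stack = ImageStack(channels=channels, voxel_size=voxel_size)
    truth = {
        "shape": list(shape),
        "voxel_size": list(voxel_size),
        "height_mu_sigma": [float(mu), float(sigma)],
        "eps_style": eps_style,
        "eps_coverage": float(eps_coverage),
        "eps_volume_per_area": float(eps_volume_per_area),
        "cells_voxels": int(cells.sum()),
        "eps_voxels": int(eps.sum()),
        "cells_mean_height_um": float((cells_vox * dz).mean()),
        "eps_mean_height_um": float((eps_vox * dz).mean()),
        "intensity": bool(intensity),
    }
    return stack, truth


@dataclass(frozen=True)
class GroupSpec:
    """Treatment-group parameters for study generation.

    Moduli are in kPa (the scale of the reported group values); Cf is the
    dimensionless biofilm momentum coefficient; ``detach_omega_mean/sd``
    parameterize where the detachment event falls on the ramp (rad/s).
    """

    label: str
    e_mean_kpa: float
    e_sd_kpa: float
    cf_mean: float
    cf_sd: float
    detach_omega_mean: float
    detach_omega_sd: float
    eps_style: str
    eps_coverage: float
    eps_volume_per_area: float


def default_study_spec(seed: int = 0) -> "StudySpec":
    """The four-group study with reported group means/SDs as defaults.

    Moduli (kPa) and momentum coefficients use the reported group values;
    the arginine group, which was not assayed by rheometry, is assigned an
    intermediate Cf.  Detachment-event locations and EPS geometry follow the
    reported qualitative directions (treated biofilms detach at lower
    velocities and carry less, more punctate EPS).
    """
    groups = [
        GroupSpec("untreated", 27.28, 8.68, 0.063, 0.021, 150.0, 15.0, "layer", 1.0, 10.0),
        GroupSpec("arginine", 15.38, 7.97, 0.055, 0.023, 100.0, 15.0, "punctate", 0.6, 8.0),
        GroupSpec("zinc", 11.14, 5.02, 0.053, 0.023, 80.0, 15.0, "punctate", 0.5, 6.0),
        GroupSpec("dza", 9.29, 2.87, 0.037, 0.023, 40.0, 15.0, "punctate", 0.3, 4.0),
    ]
    return StudySpec(groups=groups, seed=seed)


@dataclass
class StudySpec:
    """Design of one synthetic treatment study."""

    groups: list[GroupSpec]
    n_biological: int = 4
    n_technical: int = 3
    seed: int = 0
    torque_noise: float = 0.01
    force_noise: float = 0.02
    event_drop: float = 0.4
    thickness_mean_um: float = 200.0
    thickness_sd_um: float = 20.0
    torque_points: int = 72
    indentation_points: int = 800
    stack_shape: tuple[int, int, int] = (40, 64, 64)
    stack_voxel_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    include_stacks: bool = True

    def __post_init__(self) -> None:
        if self.n_biological < 1 or self.n_technical < 1:
            raise DomainError("replicate counts must be >= 1")
        for g in self.groups:
            if g.e_sd_kpa < 0 or g.cf_sd < 0:
                raise DomainError("group SDs must be non-negative")


@dataclass
class StudyData:
    """In-memory synthetic study: generated objects plus their truths."""

    spec: StudySpec
    torque: list[dict] = field(default_factory=list)       # group, replicate, curve, truth
    indentation: list[dict] = field(default_factory=list)  # group, replicate, technical, curve, truth
    stacks: list[dict] = field(default_factory=list)       # group, replicate, stack, truth

    def write(self, out_dir) -> pd.DataFrame:
        """Write CSV/TIFF files, JSON truth sidecars, and a manifest CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in self.torque:
            stem = f"torque_{rec['group']}_b{rec['replicate']}"
            path = out / f"{stem}.csv"
            write_rheometry_csv(rec["curve"], path)
            (out / f"{stem}.truth.json").write_text(json.dumps(rec["truth"]))
            rows.append({"kind": "torque", "group": rec["group"],
                         "replicate": rec["replicate"], "technical": "",
                         "path": path.name, "path2": ""})
        for rec in self.indentation:
            stem = f"indent_{rec['group']}_b{rec['replicate']}_t{rec['technical']}"
            path = out / f"{stem}.csv"
            write_indentation_csv(rec["curve"], path)
            (out / f"{stem}.truth.json").write_text(json.dumps(rec["truth"]))
            rows.append({"kind": "indentation", "group": rec["group"],
                         "replicate": rec["replicate"], "technical": rec["technical"],
                         "path": path.name, "path2": ""})
        for rec in self.stacks:
            stem = f"stack_{rec['group']}_b{rec['replicate']}"
            p_cells = out / f"{stem}_cells.tif"
            p_eps = out / f"{stem}_eps.tif"
            write_image_stack(rec["stack"], {"cells": p_cells, "eps": p_eps})
            (out / f"{stem}.truth.json").write_text(json.dumps(rec["truth"]))
            rows.append({"kind": "stack", "group": rec["group"],
                         "replicate": rec["replicate"], "technical": "",
                         "path": p_cells.name, "path2": p_eps.name})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "manifest.csv", index=False)
        meta = {"seed": self.spec.seed,
                "voxel_size_um": list(self.spec.stack_voxel_um),
                "groups": [asdict(g) for g in self.spec.groups]}
        (out / "study.json").write_text(json.dumps(meta, indent=1))
        return manifest


def _truncated_normal(gen, mean, sd, lower):
    """One draw from N(mean, sd) truncated below at ``lower`` (redraw)."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        x = gen.normal(mean, sd)
        if x >= lower:
            return x
    return lower


def generate_study(
    spec: StudySpec | None = None, out_dir=None, seed: int | None = None
) -> StudyData:
    """Generate a full treatment study; optionally write it to ``out_dir``.

    Per group × biological replicate: one torque curve (group-level Cf and
    one detachment event drawn per replicate), ``n_technical`` indentation
    curves (modulus drawn per curve from the group distribution, truncated
    at 0.5 kPa), and one two-channel stack.  Bit-reproducible from
    ``spec.seed`` (``seed`` overrides it).
    """
    if spec is None:
        spec = default_study_spec()
    if seed is not None:
        spec = StudySpec(**{**spec.__dict__, "seed": seed})
    gen = np.random.default_rng(spec.seed)
    data = StudyData(spec=spec)
    lo, hi = RAMP_RANGE
    for group in spec.groups:
        for b in range(spec.n_biological):
            cf0 = _truncated_normal(gen, group.cf_mean, group.cf_sd, 0.005)
            om_e = float(np.clip(
                gen.normal(group.detach_omega_mean, group.detach_omega_sd),
                lo * 10, hi * 0.97))
            curve, truth = generate_torque_curve(
                cf0, events=((om_e, spec.event_drop),),
                noise_sd=spec.torque_noise, n_points=spec.torque_points, rng=gen)
            truth["group"] = group.label
            data.torque.append(
                {"group": group.label, "replicate": b, "curve": curve, "truth": truth})
            for t in range(spec.n_technical):
                e_kpa = _truncated_normal(gen, group.e_mean_kpa, group.e_sd_kpa,
                                          E_TRUNCATION_KPA)
                h = _truncated_normal(gen, spec.thickness_mean_um,
                                      spec.thickness_sd_um, 100.0) * 1e-6
                delta_c = gen.uniform(40e-6, 60e-6)
                icurve, itruth = generate_indentation_curve(
                    e_kpa * 1e3, thickness_m=h, delta_contact_m=delta_c,
                    noise_sd=spec.force_noise, n_points=spec.indentation_points,
                    rng=gen)
                itruth["group"] = group.label
                data.indentation.append(
                    {"group": group.label, "replicate": b, "technical": t,
                     "curve": icurve, "truth": itruth})
            if spec.include_stacks:
                stack, struth = generate_image_stack(
                    shape=spec.stack_shape, voxel_size=spec.stack_voxel_um,
                    eps_style=group.eps_style, eps_coverage=group.eps_coverage,
                    eps_volume_per_area=group.eps_volume_per_area, rng=gen)
                struth["group"] = group.label
                data.stacks.append(
                    {"group": group.label, "replicate": b, "stack": stack,
                     "truth": struth})
    if out_dir is not None:
        data.write(out_dir)
    return data
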