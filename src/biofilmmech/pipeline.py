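"""End-to-end orchestration: study directory in, tidy report out.

``run_pipeline`` consumes a YAML-style config dict (or path), analyzes every
file listed in the study manifest (rheometry CSVs, indentation CSVs, TIFF
stacks), averages technical replicates to one value per biological replicate
(configurable), runs one-way ANOVA + Tukey per metric, computes the
zinc-arginine interaction index from the modulus table, and writes tidy CSVs.

Per-file errors never abort the batch: each failure is recorded in
``errors.csv`` and the run continues (the CLI exits nonzero when any file
failed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, indentation, interaction, rheometry
from .datatypes import ModulusTable
from .errors import BiofilmMechError, ConfigError
from .io import (
    fluid_from_config,
    geometry_from_config,
    load_config,
    probe_from_config,
    read_image_stack,
    read_indentation_csv,
    read_rheometry_csv,
)
from .stats import GroupComparison, compare_groups
from .synth import StudySpec, default_study_spec, generate_study

log = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline"]

#: Metrics compared across groups, with the per-sample table they come from.
_METRICS = (
    ("momentum_coefficient", "rheometry"),
    ("auc", "rheometry"),
    ("critical_shear_stress", "rheometry"),
    ("thickness_um", "indentation"),
    ("modulus_kpa", "indentation"),
    ("biomass_cells", "imaging"),
    ("biomass_eps", "imaging"),
    ("roughness_eps", "imaging"),
)


@dataclass
class PipelineReport:
    """All pipeline outputs, in memory."""

    rheometry: pd.DataFrame
    indentation: pd.DataFrame
    imaging: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    interaction_summary: dict
    errors: pd.DataFrame
    out_dir: Path | None = None
    failed_files: int = 0


def _per_sample_frames(cfg, study_dir, manifest):
    geometry = geometry_from_config(cfg)
    fluid = fluid_from_config(cfg)
    probe = probe_from_config(cfg)
    rheo_cfg = cfg.get("rheometry", {})
    ind_cfg = cfg.get("indentation", {})
    img_cfg = cfg.get("imaging", {})
    window = tuple(rheo_cfg.get("window", rheometry.DEFAULT_CF_WINDOW))
    threshold_sd = rheo_cfg.get("threshold_sd", 3.0)
    voxel = img_cfg.get("voxel_size_um")

    rheo_rows, ind_rows, img_rows, err_rows = [], [], [], []
    for _, row in manifest.iterrows():
        kind = row["kind"]
        path = study_dir / row["path"]
        try:
            if kind == "torque":
                curve = read_rheometry_csv(path)
                m = rheometry.analyze_torque_curve(
                    curve, geometry, fluid, window=window, threshold_sd=threshold_sd)
                rheo_rows.append({
                    "group": row["group"], "replicate": row["replicate"],
                    "momentum_coefficient": m.momentum_coefficient, "auc": m.auc,
                    "critical_shear_stress": m.critical_shear_stress,
                    "n_events": len(m.events)})
            elif kind == "indentation":
                curve = read_indentation_csv(path)
                r = indentation.analyze_indentation_curve(
                    curve, probe,
                    k_sd=ind_cfg.get("k_sd", 5.0),
                    m_run=ind_cfg.get("m_run", 10),
                    stiffening_factor=ind_cfg.get("stiffening_factor", 20.0),
                    strain_max=ind_cfg.get("strain_max", 0.20))
                ind_rows.append({
                    "group": row["group"], "replicate": row["replicate"],
                    "technical": row["technical"],
                    "delta_contact_um": r.contact.delta_contact * 1e6,
                    "thickness_um": r.contact.thickness * 1e6,
                    "slope_n_per_m": r.fit.slope, "r_squared": r.fit.r_squared,
                    "modulus_pa": r.modulus_pa,
                    "modulus_kpa": r.modulus_pa / 1e3})
            elif kind == "stack":
                if voxel is None:
                    raise ConfigError("imaging.voxel_size_um is required for stacks")
                paths = {"cells": path}
                if row.get("path2"):
                    paths["eps"] = study_dir / row["path2"]
                stack = read_image_stack(paths, voxel_size=voxel)
                q = imaging.quantify_stack(stack, method=img_cfg.get("method", "otsu"))
                rec = {"group": row["group"], "replicate": row["replicate"]}
                for role, res in q.items():
                    rec[f"biomass_{role}"] = res.biomass
                    rec[f"roughness_{role}"] = res.roughness
                img_rows.append(rec)
            else:
                raise ConfigError(f"unknown manifest kind {kind!r}")
        except (BiofilmMechError, OSError) as exc:
            log.error("%s: %s", path, exc)
            err_rows.append({"path": str(path), "kind": kind, "error": str(exc)})
    return (pd.DataFrame(rheo_rows), pd.DataFrame(ind_rows),
            pd.DataFrame(img_rows), pd.DataFrame(err_rows))


def _biological_means(frame: pd.DataFrame, value: str) -> pd.DataFrame:
    """Average technical replicates to one value per biological replicate."""
    return (frame.dropna(subset=[value])
            .groupby(["group", "replicate"], as_index=False)[value].mean())


def _grouped_values(frame: pd.DataFrame, value: str) -> dict[str, np.ndarray]:
    if frame.empty or value not in frame.columns:
        return {}
    agg = _biological_means(frame, value)
    return {g: sub[value].to_numpy() for g, sub in agg.groupby("group")}


def run_pipeline(config, out_dir=None) -> PipelineReport:
    """Run every stage described by ``config`` and write a report directory.

    ``config`` is a dict or a YAML path.  Keys (all optional unless noted):
    ``study_dir`` (directory holding ``manifest.csv``) or ``synthetic``
    (StudySpec overrides; a study is generated into ``out_dir/inputs``),
    ``geometry``, ``fluid``, ``probe``, ``rheometry`` (window,
    threshold_sd), ``indentation`` (k_sd, m_run, stiffening_factor,
    strain_max), ``imaging`` (method, voxel_size_um), ``alpha``, ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    out = Path(out_dir) if out_dir is not None else (
        Path(cfg["output_dir"]) if "output_dir" in cfg else None)

    if "study_dir" in cfg:
        study_dir = Path(cfg["study_dir"])
    elif "synthetic" in cfg or cfg.get("generate", False):
        if out is None:
            raise ConfigError("synthetic runs need an output directory")
        spec = default_study_spec(seed=cfg.get("seed", 0))
        overrides = cfg.get("synthetic") or {}
        if overrides:
            spec = StudySpec(**{**spec.__dict__, **overrides})
        study_dir = out / "inputs"
        generate_study(spec, out_dir=study_dir)
        cfg.setdefault("imaging", {}).setdefault(
            "voxel_size_um", list(spec.stack_voxel_um))
    else:
        raise ConfigError("config needs either 'study_dir' or 'synthetic'")

    manifest_path = study_dir / "manifest.csv"
    if not manifest_path.exists():
        raise ConfigError(f"{manifest_path} not found")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)

    rheo, ind, img, errors = _per_sample_frames(cfg, study_dir, manifest)

    alpha = cfg.get("alpha", 0.05)
    comparisons: dict[str, GroupComparison] = {}
    frames = {"rheometry": rheo, "indentation": ind, "imaging": img}
    for metric, source in _METRICS:
        values = _grouped_values(frames[source], metric)
        values = {g: v for g, v in values.items() if v.size >= 2}
        if len(values) < 2:
            continue
        try:
            comparisons[metric] = compare_groups(values, alpha=alpha, metric=metric)
        except BiofilmMechError as exc:
            log.error("group comparison for %s failed: %s", metric, exc)

    interaction_summary: dict = {}
    try:
        table = ModulusTable()
        for _, row in _biological_means(ind, "modulus_pa").iterrows():
            table.add(row["group"], str(row["replicate"]), row["modulus_pa"])
        mean_iai, sd_iai, values = interaction.replicate_interaction_summary(table)
        diff_ratio = interaction.replicate_difference_ratio_summary(table)
        interaction_summary = {
            "iai_mean": mean_iai, "iai_sd": sd_iai,
            "iai_classification": interaction.classify_interaction(mean_iai),
            "per_replicate": values, **diff_ratio,
        }
    except BiofilmMechError as exc:
        log.error("interaction-index stage failed: %s", exc)
        interaction_summary = {"error": str(exc)}

    report = PipelineReport(
        rheometry=rheo, indentation=ind, imaging=img,
        comparisons=comparisons, interaction_summary=interaction_summary,
        errors=errors, out_dir=out, failed_files=len(errors),
    )
    if out is not None:
        _write_report(report, out)
    return report


def _write_report(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.rheometry.to_csv(out / "rheometry_per_coupon.csv", index=False)
    report.indentation.to_csv(out / "indentation_per_curve.csv", index=False)
    report.imaging.to_csv(out / "imaging_per_stack.csv", index=False)
    report.errors.to_csv(out / "errors.csv", index=False)
    for metric, comp in report.comparisons.items():
        comp.group_stats.to_csv(out / f"groups_{metric}.csv", index=False)
        pw = comp.pairwise.copy()
        pw.insert(0, "metric", metric)
        pw.insert(1, "anova_f", comp.anova_f)
        pw.insert(2, "anova_p", comp.anova_p)
        pw.to_csv(out / f"pairwise_{metric}.csv", index=False)
    pd.DataFrame([{k: v for k, v in report.interaction_summary.items()
                   if k != "per_replicate"}]).to_csv(
        out / "interaction_summary.csv", index=False)
    if "per_replicate" in report.interaction_summary:
        pd.DataFrame({"iai": report.interaction_summary["per_replicate"]}).to_csv(
            out / "interaction_per_replicate.csv", index=False)
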