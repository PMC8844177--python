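"""End-to-end orchestration: simulate -> score -> AI maps -> GLM -> report.

A study run is driven by a :class:`StudyConfig` (YAML-loadable).  Stages run
in the order the analysis requires: behavioural scoring and QC, symmetric
template construction, smoothing, asymmetry-index maps, voxel-wise GLM,
whole-brain cluster correction, ROI analysis, post-hoc hemisphere-wise peak
correlations, and an optional sensitivity refit on a subject subset.  Every
output file is recorded in a run manifest with a content hash; identical
configs and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import (
    build_symmetric_template,
    compute_ai_map,
    default_ai_floor,
    smooth,
)
from .dichotic import score_cohort
from .glm import (
    build_design,
    compare_maps,
    fit_voxelwise,
    peak_posthoc,
    roi_analysis,
    whole_brain_clusters,
)
from .simulate import (
    CohortSpec,
    PlantedEffect,
    TemplateGrid,
    make_roi_masks,
    simulate_behaviour,
    simulate_covariates,
    simulate_volumes,
)

__all__ = ["StudyConfig", "RunManifest", "run_pipeline", "summarize_cohort"]

logger = logging.getLogger("dlasym")


@dataclass
class StudyConfig:
    """Configuration for a full synthetic study run.

    Defaults are the analysis conventions used throughout: smoothing sigma
    2.55 mm (FWHM 6 mm), whole-brain cluster-forming threshold Z > 3.09 with
    cluster-level alpha 0.05, ROI threshold Z > 2.58 with Bonferroni over the
    three regions, 26-connectivity, and an AI denominator floor at 10% of the
    template mean.
    """

    seed: int = 0
    n_subjects: int = 281
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    smoothing_sigma_mm: float = 2.55
    threshold_z: float = 3.09
    roi_threshold_z: float = 2.58
    alpha: float = 0.05
    connectivity: int = 26
    floor_fraction: float = 0.10
    effects: list[dict] = field(default_factory=list)
    exclude_subjects: list[str] = field(default_factory=list)
    exclude_left_handers: bool = False
    outdir: str = "dlasym_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("grid_shape", "voxel_size_mm"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def planted_effects(self) -> list[PlantedEffect]:
        return [
            PlantedEffect(
                center_voxel=tuple(e["center_voxel"]),
                radius_mm=float(e["radius_mm"]),
                beta=float(e["beta"]),
                hemisphere_mode=e.get("hemisphere_mode", "right_driven"),
            )
            for e in self.effects
        ]


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, versions, output hashes."""

    config: dict
    seed: int
    version: str
    started_utc: str
    finished_utc: str = ""
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_log: list[str] = field(default_factory=list)

    def add_output(self, path: Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = h

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def summarize_cohort(scores: pd.DataFrame) -> dict:
    """Cohort-level laterality summary: n, mean, SD, % negative, % zero.

    Operates on QC-passing subjects with a defined LI; also returns histogram
    counts (5-point bins spanning [-100, 100]) for distribution plots.
    """
    ok = scores[scores["qc_pass"] & scores["li"].notna()]
    if len(ok) == 0:
        raise ValueError("empty cohort after QC")
    li = ok["li"].to_numpy(dtype=float)
    edges = np.arange(-102.5, 107.5, 5.0)
    hist, _ = np.histogram(li, bins=edges)
    return {
        "n": int(len(li)),
        "mean": float(li.mean()),
        "sd": float(li.std(ddof=1)),
        "pct_negative": float(100.0 * (li < 0).mean()),
        "pct_zero": float(100.0 * (li == 0).mean()),
        "hist_bin_edges": edges.tolist(),
        "hist_counts": hist.tolist(),
    }


def analyze_ai_study(
    volumes: np.ndarray,
    grid: TemplateGrid,
    mask: np.ndarray,
    covariates: pd.DataFrame,
    li: np.ndarray,
    sigma_mm: float = 2.55,
    floor_fraction: float = 0.10,
    keep_residuals: bool = True,
):
    """Smooth volumes, build AI maps, and fit the voxel-wise GLM in one call.

    Convenience wrapper for the smooth -> AI -> GLM core used by the full
    pipeline, simulation studies and calibration tests.  Returns
    ``(glm_result, ai_stack, smoothed, valid_mask)``.
    """
    template = build_symmetric_template(volumes)
    smoothed = smooth(volumes, grid, sigma_mm)
    floor = default_ai_floor(template, mask, floor_fraction)
    half = grid.shape[0] // 2
    half_mask = mask[:half] & np.flip(mask, axis=0)[:half]
    left = smoothed[:, :half].astype(np.float64)
    right = np.flip(smoothed, axis=1)[:, :half].astype(np.float64)
    denom = 0.5 * (left + right)
    valid = half_mask & np.all(denom > floor, axis=0)
    ai_stack = np.zeros_like(denom)
    np.divide(left - right, denom, out=ai_stack, where=denom > 0)
    design = build_design(covariates.reset_index(drop=True), li)
    result = fit_voxelwise(ai_stack, design, mask=valid,
                           keep_residuals=keep_residuals, grid=grid)
    return result, ai_stack, smoothed, valid


def _fit_study(ai_stack, mask, covariates, li, exclude_ids):
    keep = ~covariates["subject_id"].isin(exclude_ids).to_numpy()
    design = build_design(covariates[keep].reset_index(drop=True), li[keep])
    result = fit_voxelwise(ai_stack[keep], design, mask=mask)
    return result, keep


def run_pipeline(config: StudyConfig) -> RunManifest:
    """Run the full synthetic study and write all outputs under ``config.outdir``.

    Deterministic given the config (seed included).  Returns the manifest;
    raises with the stage name on failure.
    """
    manifest = RunManifest(
        config=asdict(config), seed=config.seed, version=__version__,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage = "simulate-behaviour"
    try:
        spec = CohortSpec(n_subjects=config.n_subjects, seed=config.seed)
        grid = TemplateGrid(shape=config.grid_shape,
                            voxel_size_mm=config.voxel_size_mm)
        trials, setup, truth = simulate_behaviour(spec, rng)
        covariates = simulate_covariates(spec, rng)
        manifest.stage_log.append(
            f"{stage}: {config.n_subjects} subjects, {len(trials)} trials")

        stage = "score"
        scores = score_cohort(trials, setup)
        scores = scores.merge(covariates, on="subject_id")
        usable = scores[scores["qc_pass"] & scores["li"].notna()].reset_index(drop=True)
        manifest.stage_log.append(
            f"{stage}: {len(scores)} scored, {len(scores) - len(usable)} excluded by QC, "
            f"{len(usable)} usable")
        if config.exclude_left_handers:
            usable = usable[usable["handedness"] != "left"].reset_index(drop=True)
            manifest.stage_log.append(
                f"{stage}: left-handers excluded, {len(usable)} remain")
        if len(usable) == 0:
            raise ValueError("cohort empty after QC")
        summary = summarize_cohort(scores)
        p = outdir / "cohort_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest.add_output(p)
        p = outdir / "laterality_scores.tsv"
        scores.to_csv(p, sep="\t", index=False)
        manifest.add_output(p)

        stage = "simulate-volumes"
        li = usable["li"].to_numpy(dtype=float)
        study = simulate_volumes(
            spec, grid, config.planted_effects(), li,
            covariates=usable, rng=rng,
        )
        manifest.stage_log.append(
            f"{stage}: {study.volumes.shape[0]} volumes on grid {grid.shape}, "
            f"{int(study.mask.sum())} mask voxels")

        stage = "template"
        template = build_symmetric_template(study.volumes)

        stage = "smooth+ai"
        smoothed = smooth(study.volumes, grid, config.smoothing_sigma_mm)
        floor = default_ai_floor(template, study.mask, config.floor_fraction)
        half = grid.shape[0] // 2
        half_mask = study.mask[:half] & np.flip(study.mask, axis=0)[:half]
        ai_stack = np.empty((smoothed.shape[0], half, *grid.shape[1:]))
        valid = half_mask.copy()
        for s in range(smoothed.shape[0]):
            ai = compute_ai_map(smoothed[s], grid, floor)
            ai_stack[s] = ai.data
            valid &= ai.valid_mask
        manifest.stage_log.append(
            f"{stage}: sigma {config.smoothing_sigma_mm} mm, floor {floor:.4f}, "
            f"{int(valid.sum())} valid half-grid voxels")

        stage = "glm"
        result, _ = _fit_study(ai_stack, valid, usable, li, config.exclude_subjects)
        manifest.stage_log.append(
            f"{stage}: df {result.df}, residual FWHM "
            f"{np.round(result.residual_fwhm_mm, 2).tolist()} mm")

        stage = "clusters"
        report = whole_brain_clusters(
            result, config.threshold_z, config.alpha, config.connectivity)
        p = outdir / "clusters.tsv"
        report.to_frame().to_csv(p, sep="\t", index=False, float_format="%.4g")
        manifest.add_output(p)
        manifest.stage_log.append(
            f"{stage}: {len(report.clusters)} clusters, "
            f"{len(report.significant)} significant at alpha {config.alpha}")

        stage = "roi"
        roi_masks = make_roi_masks(grid)
        roi_results = roi_analysis(
            result, roi_masks, config.roi_threshold_z, config.alpha,
            config.connectivity)
        rows = []
        for rr in roi_results:
            for c in rr.clusters:
                rows.append({
                    "region": rr.region_name, "size_voxels": c.size_voxels,
                    "grf_p": c.grf_p, "peak_z": c.peak_z,
                    "direction": c.direction,
                    "bonferroni_alpha": rr.bonferroni_alpha,
                    "significant": c.grf_p < rr.bonferroni_alpha,
                })
        p = outdir / "roi_clusters.tsv"
        pd.DataFrame(rows, columns=[
            "region", "size_voxels", "grf_p", "peak_z", "direction",
            "bonferroni_alpha", "significant"]).to_csv(
            p, sep="\t", index=False, float_format="%.4g")
        manifest.add_output(p)

        stage = "posthoc"
        rows = []
        for c in report.significant + [c for rr in roi_results for c in rr.significant]:
            pc = peak_posthoc(c.peak_voxel, smoothed, ai_stack, li, grid)
            rows.append({
                "peak_i": c.peak_voxel[0], "peak_j": c.peak_voxel[1],
                "peak_k": c.peak_voxel[2], "label": c.label or "",
                "r_ai": pc.r_ai, "p_ai": pc.p_ai,
                "r_left": pc.r_left, "p_left": pc.p_left,
                "r_right": pc.r_right, "p_right": pc.p_right,
            })
        p = outdir / "peak_correlations.tsv"
        pd.DataFrame(rows, columns=[
            "peak_i", "peak_j", "peak_k", "label", "r_ai", "p_ai",
            "r_left", "p_left", "r_right", "p_right"]).to_csv(
            p, sep="\t", index=False, float_format="%.4g")
        manifest.add_output(p)

        sens = {}
        if config.exclude_subjects:
            stage = "sensitivity"
            full_result, _ = _fit_study(ai_stack, valid, usable, li, [])
            r, pval = compare_maps(result.z_map, full_result.z_map, result.mask)
            sens = {"excluded": list(config.exclude_subjects),
                    "map_correlation_r": r, "map_correlation_p": pval}
            p = outdir / "sensitivity.json"
            with open(p, "w") as fh:
                json.dump(sens, fh, indent=2)
            manifest.add_output(p)
            manifest.stage_log.append(
                f"{stage}: map correlation with full fit r = {r:.3f}")

        stage = "report"
        _write_report(outdir / "report.txt", summary, scores, report,
                      roi_results, rows, manifest)
        manifest.add_output(outdir / "report.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest


def _write_report(path, summary, scores, cluster_report, roi_results,
                  posthoc_rows, manifest) -> None:
    acc_cols = [c for c in scores.columns if c.startswith("acc_")
                and "share" not in c]
    lines = [
        "Dichotic listening / grey-matter asymmetry study report",
        "=" * 56,
        "",
        f"Cohort: n = {summary['n']} usable subjects",
        f"Laterality index: mean {summary['mean']:.1f}, SD {summary['sd']:.1f}, "
        f"{summary['pct_negative']:.0f}% negative, {summary['pct_zero']:.0f}% zero",
        "",
        "Category accuracies (mean over subjects):",
    ]
    for c in acc_cols:
        lines.append(f"  {c.removeprefix('acc_'):>4}: {scores[c].mean():.3f}")
    lines += ["", f"Whole-brain clusters (Z > {cluster_report.threshold_z}, "
              f"alpha {cluster_report.alpha}):"]
    if not cluster_report.clusters:
        lines.append("  none")
    for c in cluster_report.clusters[:10]:
        lines.append(
            f"  size = {c.size_voxels} voxels, p = {c.grf_p:.4g}; peak Z = "
            f"{c.peak_z:.2f} at ({c.peak_world_mm[0]:.0f}, "
            f"{c.peak_world_mm[1]:.0f}, {c.peak_world_mm[2]:.0f}) mm "
            f"[{c.direction}]")
    lines += ["", "ROI clusters (Bonferroni-corrected):"]
    any_roi = False
    for rr in roi_results:
        for c in rr.clusters:
            any_roi = True
            sig = "significant" if c.grf_p < rr.bonferroni_alpha else "n.s."
            lines.append(
                f"  {rr.region_name}: size = {c.size_voxels}, p = {c.grf_p:.4g} "
                f"({sig} at {rr.bonferroni_alpha:.3f}) [{c.direction}]")
    if not any_roi:
        lines.append("  none")
    lines += ["", "Post-hoc peak correlations (LI vs AI / left / right volume):"]
    if not posthoc_rows:
        lines.append("  none")
    for row in posthoc_rows:
        lines.append(
            f"  peak ({row['peak_i']},{row['peak_j']},{row['peak_k']}) "
            f"{row['label']}: AI r = {row['r_ai']:.2f} (p = {row['p_ai']:.3g}); "
            f"left r = {row['r_left']:.2f} (p = {row['p_left']:.3g}); "
            f"right r = {row['r_right']:.2f} (p = {row['p_right']:.3g})")
    lines += ["", "Stage log:"] + [f"  {s}" for s in manifest.stage_log] + [""]
    Path(path).write_text("\n".join(lines))
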