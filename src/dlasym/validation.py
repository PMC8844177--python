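"""Simulation-based validation studies: error-rate calibration and power.

Reusable harnesses that exercise the full generator -> asymmetry-map -> GLM
-> cluster-inference chain on synthetic studies:

* :func:`simulate_and_fit` — one complete synthetic study, fitted.
* :func:`family_wise_error_rate` — the proportion of null studies (no planted
  effect) with any whole-brain-significant cluster, for checking that the
  GRF cluster correction controls the family-wise error rate.
* :func:`permutation_max_cluster_sizes` — a permutation oracle for the null
  distribution of the maximum cluster extent, against which the GRF cluster
  p can be compared.
* :func:`planted_effect_replicates` — power and localisation of a planted
  hemispheric effect, plus the post-hoc hemisphere-wise decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import (
    build_design,
    extract_clusters,
    fit_voxelwise,
    grf_cluster_p,
    peak_posthoc,
    whole_brain_clusters,
)
from .pipeline import analyze_ai_study
from .simulate import (
    CohortSpec,
    PlantedEffect,
    TemplateGrid,
    simulate_covariates,
    simulate_li,
    simulate_volumes,
)

__all__ = [
    "FittedStudy",
    "simulate_and_fit",
    "family_wise_error_rate",
    "permutation_max_cluster_sizes",
    "attenuation_from_smoothing",
    "beta_for_peak_z",
    "planted_effect_replicates",
]

DEFAULT_EFFECT_CENTER = (10, 24, 20)  # left-hemisphere voxel on the 40x48x40 grid


@dataclass
class FittedStudy:
    """One synthetic study taken through smoothing, AI maps and the GLM."""

    li: np.ndarray
    covariates: pd.DataFrame
    result: object  # GLMResult
    ai: np.ndarray
    smoothed: np.ndarray
    valid: np.ndarray
    grid: TemplateGrid


def simulate_and_fit(
    seed: int,
    n_subjects: int = 60,
    effects: list[PlantedEffect] | None = None,
    grid: TemplateGrid | None = None,
    sigma_mm: float = 2.55,
    keep_residuals: bool = True,
) -> FittedStudy:
    """Generate one synthetic study and run the analysis chain on it."""
    if grid is None:
        grid = TemplateGrid()
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    truth = simulate_li(spec, rng)
    li = truth["li"].to_numpy()
    ok = np.isfinite(li)
    cov = simulate_covariates(spec, rng)[ok].reset_index(drop=True)
    study = simulate_volumes(spec, grid, effects or [], li[ok],
                             covariates=cov, rng=rng)
    result, ai, smoothed, valid = analyze_ai_study(
        study.volumes, grid, study.mask, cov, li[ok], sigma_mm=sigma_mm,
        keep_residuals=keep_residuals,
    )
    return FittedStudy(li=li[ok], covariates=cov, result=result, ai=ai,
                       smoothed=smoothed, valid=valid, grid=grid)


def family_wise_error_rate(
    n_studies: int,
    seed: int,
    n_subjects: int = 60,
    threshold_z: float = 3.09,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> dict:
    """Proportion of null studies with any whole-brain-significant cluster.

    Each replicate is a complete null study (fresh laterality indices,
    covariates and volumes; no planted effect); both map signs are analysed,
    as in the study pipeline.  Under exact error control the rate equals
    ``alpha``; the GRF approximation makes it deviate somewhat.
    """
    n_sig = 0
    min_ps = np.ones(n_studies)
    for rep in range(n_studies):
        fs = simulate_and_fit(seed + rep, n_subjects=n_subjects)
        report = whole_brain_clusters(fs.result, threshold_z, alpha,
                                      connectivity)
        if report.clusters:
            min_ps[rep] = min(c.grf_p for c in report.clusters)
        if report.significant:
            n_sig += 1
    return {"rate": n_sig / n_studies, "n_studies": n_studies,
            "min_ps": min_ps}


def permutation_max_cluster_sizes(
    fs: FittedStudy,
    n_permutations: int,
    seed: int,
    threshold_z: float = 3.09,
    connectivity: int = 26,
) -> np.ndarray:
    """Null distribution of the maximum positive-cluster extent by permutation.

    Permutes the laterality index across subjects (exchangeable under the
    null), refits the voxel-wise GLM, and records the largest cluster of
    ``Z > threshold_z``.  The resulting ``P(max >= k)`` is the permutation
    analogue of the one-sided GRF cluster-corrected p.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(n_permutations, dtype=int)
    for b in range(n_permutations):
        li_p = rng.permutation(fs.li)
        design = build_design(fs.covariates, li_p)
        r = fit_voxelwise(fs.ai, design, mask=fs.valid, keep_residuals=False,
                          grid=fs.grid)
        cs = extract_clusters(r.z_map, threshold_z, connectivity)
        out[b] = max((c.size_voxels for c in cs), default=0)
    return out


def attenuation_from_smoothing(effect_radius_mm: float, sigma_mm: float) -> float:
    """Peak attenuation of a Gaussian-profile effect under Gaussian smoothing.

    An effect with radial profile sd ``s = radius/2`` convolved with an
    isotropic kernel of sd ``sigma`` keeps the fraction
    ``(s^2 / (s^2 + sigma^2))^{3/2}`` of its peak amplitude.
    """
    s2 = (effect_radius_mm / 2.0) ** 2
    return (s2 / (s2 + sigma_mm**2)) ** 1.5


def beta_for_peak_z(
    target_z: float,
    ai_noise_sd: float,
    li_sd: float,
    n_subjects: int,
    effect_radius_mm: float = 12.0,
    sigma_mm: float = 2.55,
) -> float:
    """Effect slope giving an expected peak Z of ``target_z`` after smoothing.

    From the GLM standard error, ``E[t] ~ beta * sd(li) * sqrt(n) / sd(AI)``
    at the effect centre; the planted amplitude is divided by the smoothing
    attenuation so the target refers to the analysed (smoothed) maps.
    """
    atten = attenuation_from_smoothing(effect_radius_mm, sigma_mm)
    return target_z * ai_noise_sd / (li_sd * np.sqrt(n_subjects) * atten)


def planted_effect_replicates(
    n_replicates: int,
    seed: int,
    n_subjects: int = 281,
    target_peak_z: float = 5.0,
    effect_center: tuple[int, int, int] = DEFAULT_EFFECT_CENTER,
    effect_radius_mm: float = 12.0,
    hemisphere_mode: str = "right_driven",
    threshold_z: float = 3.09,
    alpha: float = 0.05,
) -> dict:
    """Detection rate and post-hoc decomposition for a planted effect.

    The effect slope is derived from a pilot null study (AI noise SD at the
    effect centre) so the expected peak Z is ``target_peak_z`` at the given
    cohort size.  A replicate counts as detected when a significant cluster
    of the expected (positive) direction peaks within one residual FWHM of
    the planted centre.
    """
    grid = TemplateGrid()
    pilot = simulate_and_fit(seed, n_subjects=n_subjects, keep_residuals=True)
    ci = effect_center
    ai_sd = float(pilot.ai[:, ci[0], ci[1], ci[2]].std())
    li_sd = float(pilot.li.std())
    beta = beta_for_peak_z(target_peak_z, ai_sd, li_sd, n_subjects,
                           effect_radius_mm)
    effect = PlantedEffect(effect_center, effect_radius_mm, beta,
                           hemisphere_mode)
    xw, yw, zw = grid.world_coords()
    center_mm = np.array([xw[ci[0]], yw[ci[1]], zw[ci[2]]])

    detected = 0
    r_left, r_right, peak_zs = [], [], []
    for rep in range(n_replicates):
        fs = simulate_and_fit(seed + 1 + rep, n_subjects=n_subjects,
                              effects=[effect])
        report = whole_brain_clusters(fs.result, threshold_z, alpha)
        fwhm = float(np.mean(fs.result.residual_fwhm_mm))
        hit = None
        for c in report.significant:
            if c.direction != "positive":
                continue
            dist = np.linalg.norm(np.array(c.peak_world_mm) - center_mm)
            if dist <= fwhm:
                hit = c
                break
        if hit is not None:
            detected += 1
            peak_zs.append(hit.peak_z)
            pc = peak_posthoc(hit.peak_voxel, fs.smoothed, fs.ai, fs.li, grid)
            r_left.append(pc.r_left)
            r_right.append(pc.r_right)
    return {
        "detection_rate": detected / n_replicates,
        "n_replicates": n_replicates,
        "beta": beta,
        "mean_peak_z": float(np.mean(peak_zs)) if peak_zs else float("nan"),
        "r_left": np.array(r_left),
        "r_right": np.array(r_right),
    }
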