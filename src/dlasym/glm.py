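"""Mass-univariate GLM on asymmetry maps with Gaussian random-field cluster inference.

The model regresses, at every valid half-grid voxel, the asymmetry index on
the dichotic-listening laterality index with confound covariates (age at
scan, years elapsed between scan and task, sex, and scanner as dummy codes).
The per-voxel t statistic for the laterality regressor is converted to a Z
score by probability matching, clusters of supra-threshold voxels are formed
under a declared connectivity, and each cluster receives a family-wise
corrected p value from Gaussian random-field (GRF) cluster-extent theory:

    E[m]        = R * (4 ln 2)^{3/2} (2 pi)^{-2} (z^2 - 1) exp(-z^2 / 2)
    P(n >= k)   = exp(-beta * k^{2/3}),  beta = (Gamma(5/2) / E[n])^{2/3}
    p_cluster   = 1 - exp(-E[m] * P(n >= k))

where R is the search volume in resels (voxels scaled by the estimated
residual smoothness), E[m] the expected number of clusters at the
cluster-forming threshold z, and E[n] = V * Phi(-z) / E[m] the expected
cluster size in voxels.  Residual smoothness is estimated from the variance
of spatial first differences of standardised GLM residuals.

Because cluster correction on a Z map is one-sided, both signs are analysed
(the map and its negation) and each cluster is reported with its direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .asymmetry import AsymmetryImage, half_grid_world, hemisphere_values_at
from .simulate import TemplateGrid

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "Cluster",
    "ClusterReport",
    "RoiResult",
    "PeakCorrelations",
    "build_design",
    "fit_voxelwise",
    "t_to_z",
    "estimate_smoothness",
    "extract_clusters",
    "grf_cluster_p",
    "whole_brain_clusters",
    "roi_analysis",
    "peak_posthoc",
    "compare_maps",
]

_GAMMA_5_2 = special.gamma(2.5)  # Gamma(D/2 + 1) for D = 3


@dataclass
class DesignMatrix:
    """Design with the laterality index as the single effect of interest."""

    matrix: np.ndarray  # (n_subjects, n_columns)
    columns: list[str]
    li_index: int
    subject_ids: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design(covariates: pd.DataFrame, li: np.ndarray | None = None) -> DesignMatrix:
    """Assemble the design: intercept, LI, age, years elapsed, sex, scanner dummies.

    ``covariates`` needs columns ``subject_id``, ``age_at_scan``,
    ``years_elapsed``, ``sex`` and ``scanner``; the laterality index comes
    either from an ``li`` array aligned with the rows or a ``li`` column.
    Scanner uses reference-cell dummy coding (first level alphabetically is
    the reference), giving k-1 columns for k levels.  Raises on missing
    values or a rank-deficient design, naming the offending columns.
    """
    cov = covariates.reset_index(drop=True)
    if li is None:
        if "li" not in cov.columns:
            raise ValueError("laterality index not provided")
        li = cov["li"].to_numpy(dtype=float)
    li = np.asarray(li, dtype=float)
    if len(li) != len(cov):
        raise ValueError("li length does not match covariate rows")

    needed = ["age_at_scan", "years_elapsed", "sex"]
    cols = [np.ones(len(cov)), li] + [cov[c].to_numpy(dtype=float) for c in needed]
    names = ["intercept", "li", "age_at_scan", "years_elapsed", "sex"]
    levels = sorted(cov["scanner"].astype(str).unique())
    for lev in levels[1:]:
        cols.append((cov["scanner"].astype(str) == lev).to_numpy(dtype=float))
        names.append(f"scanner[{lev}]")
    X = np.column_stack(cols)
    if np.any(~np.isfinite(X)):
        bad = [names[j] for j in range(X.shape[1]) if np.any(~np.isfinite(X[:, j]))]
        raise ValueError(f"missing or non-finite covariates in columns: {bad}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name columns that are linearly dependent on the preceding ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")
    return DesignMatrix(
        matrix=X, columns=names, li_index=1,
        subject_ids=[str(s) for s in cov["subject_id"]],
    )


@dataclass
class GLMResult:
    """Per-voxel statistics for the laterality regressor, on the half-grid."""

    beta_map: np.ndarray
    t_map: np.ndarray
    z_map: np.ndarray
    mask: np.ndarray  # voxels analysed (valid AI + non-degenerate residuals)
    df: int
    residual_fwhm_mm: np.ndarray  # per-axis estimate
    n_mask_voxels: int
    grid: TemplateGrid
    residuals: np.ndarray | None = None  # (n, X/2, Y, Z) standardised if kept


def t_to_z(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Probability-matching t -> Z transform, sign-preserving.

    ``z = Phi^{-1}(F_t(t; df))`` computed in log-tail space
    (``ndtri_exp(log F)``) so extreme |t| do not saturate at |z| ~ 8.
    """
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        log_tail = stats.t.logsf(np.abs(t_arr), df)
        z = -special.ndtri_exp(log_tail)
    z = np.where(np.isnan(t_arr), np.nan, np.sign(t_arr) * z)
    return float(z) if np.isscalar(t) else z


def fit_voxelwise(
    ai_images: list[AsymmetryImage] | np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    keep_residuals: bool = True,
    grid: TemplateGrid | None = None,
) -> GLMResult:
    """Ordinary least squares per voxel; t and Z maps for the LI coefficient.

    ``ai_images`` is a list of per-subject :class:`AsymmetryImage` (shared
    grid) or a pre-stacked ``(n, X/2, Y, Z)`` array (then ``mask`` is
    required).  Analysis is restricted to the intersection of the subjects'
    valid masks; voxels with zero residual variance are dropped from the
    analysis mask.
    """
    if isinstance(ai_images, np.ndarray):
        if mask is None:
            raise ValueError("mask required with a pre-stacked AI array")
        Y4 = np.asarray(ai_images, dtype=np.float64)
    else:
        grid = ai_images[0].grid
        mask_ = ai_images[0].valid_mask.copy()
        for img in ai_images[1:]:
            if img.data.shape != ai_images[0].data.shape:
                raise ValueError("AI maps do not share a grid")
            mask_ &= img.valid_mask
        mask = mask_ if mask is None else (mask & mask_)
        Y4 = np.stack([img.data for img in ai_images]).astype(np.float64)
    if grid is None:
        # infer a grid for reporting: half-grid shape doubled in x
        hx, hy, hz = Y4.shape[1:]
        grid = TemplateGrid(shape=(2 * hx, hy, hz))

    X = design.matrix
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few subjects for the design")
    if Y4.shape[0] != n:
        raise ValueError("AI stack and design have different subject counts")

    Y = Y4[:, mask]  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    c = xtx_inv[design.li_index, design.li_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(c * sigma2)
        t = beta[design.li_index] / se
    # zero residual variance (relative to the data scale) -> t undefined
    scale = np.maximum((Y**2).mean(axis=0), np.finfo(float).tiny)
    good = sigma2 > 1e-20 * scale
    t[~good] = np.nan

    final_mask = mask.copy()
    idx = np.flatnonzero(mask.ravel())
    bad_idx = idx[~good]
    final_mask.ravel()[bad_idx] = False

    beta_map = np.zeros(mask.shape)
    t_map = np.full(mask.shape, np.nan)
    beta_map[mask] = beta[design.li_index]
    t_map[mask] = t
    t_map[~final_mask] = np.nan
    z_map = np.where(final_mask, t_to_z(np.nan_to_num(t_map), df), np.nan)

    # standardise residuals voxel-wise for smoothness estimation
    resid4 = None
    fwhm = np.full(3, np.nan)
    if keep_residuals:
        with np.errstate(divide="ignore", invalid="ignore"):
            std_resid = resid / np.sqrt(sigma2 * df)
        std_resid[:, ~good] = 0.0
        resid4 = np.zeros((n, *mask.shape))
        resid4[:, mask] = std_resid
        fwhm = estimate_smoothness(resid4, final_mask, grid.voxel_size_mm)

    return GLMResult(
        beta_map=beta_map, t_map=t_map, z_map=z_map, mask=final_mask, df=df,
        residual_fwhm_mm=fwhm, n_mask_voxels=int(final_mask.sum()), grid=grid,
        residuals=resid4,
    )


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Per-axis residual FWHM (mm) from first differences of standardised residuals.

    For a stationary Gaussian field with Gaussian autocorrelation, adjacent
    standardised values at spacing ``D`` have correlation
    ``rho = exp(-D^2 / (4 sigma^2))``; the variance of their difference is
    ``2 (1 - rho)``, so ``sigma^2 = -D^2 / (4 ln rho)`` and
    ``FWHM = sqrt(8 ln 2) * sigma``.  Estimates below one voxel (including
    the white-noise limit rho <= 0) are clamped to the voxel size.
    """
    if mask.sum() < 100:
        raise ValueError("mask too small for smoothness estimation (<100 voxels)")
    res = np.asarray(residuals, dtype=np.float64)
    if res.ndim == 3:
        res = res[None]
    # re-standardise voxel-wise so the estimate is scale invariant
    sd = res[:, mask].std(axis=0, ddof=0).mean()
    fwhm = np.empty(3)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair_mask = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        diffs = (res[(slice(None), *sl_a)] - res[(slice(None), *sl_b)])[:, pair_mask]
        v = float((diffs**2).mean()) / (sd**2 if sd > 0 else 1.0)
        rho = 1.0 - v / 2.0
        d = voxel_size_mm[ax]
        if rho <= 0.0:
            fwhm[ax] = d  # white-noise limit: clamp at voxel size
            continue
        sigma2 = -d * d / (4.0 * np.log(rho))
        fwhm[ax] = max(np.sqrt(8.0 * np.log(2.0) * sigma2), d)
    return fwhm


@dataclass
class Cluster:
    """One supra-threshold cluster."""

    size_voxels: int
    peak_z: float
    peak_voxel: tuple[int, int, int]
    peak_world_mm: tuple[float, float, float]
    direction: str = "positive"
    grf_p: float = float("nan")
    label: str | None = None
    voxels: np.ndarray | None = None  # (k, 3) indices


@dataclass
class ClusterReport:
    """Thresholded clusters with GRF-corrected p values, sorted by p."""

    clusters: list[Cluster]
    threshold_z: float
    alpha: float
    n_mask_voxels: int
    residual_fwhm_mm: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.grf_p < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "size_voxels": c.size_voxels,
                    "grf_p": c.grf_p,
                    "peak_z": c.peak_z,
                    "peak_i": c.peak_voxel[0],
                    "peak_j": c.peak_voxel[1],
                    "peak_k": c.peak_voxel[2],
                    "peak_x_mm": c.peak_world_mm[0],
                    "peak_y_mm": c.peak_world_mm[1],
                    "peak_z_mm": c.peak_world_mm[2],
                    "direction": c.direction,
                    "label": c.label or "",
                }
                for c in self.clusters
            ]
        )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_clusters(
    z_map: np.ndarray,
    threshold_z: float,
    connectivity: int = 26,
    grid: TemplateGrid | None = None,
    keep_voxels: bool = False,
) -> list[Cluster]:
    """Connected components of {Z > threshold} under 6/18/26-connectivity.

    Peak = the voxel with maximum Z in the cluster; ties broken by lowest
    linear voxel index.  NaNs are treated as sub-threshold.
    """
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    z = np.nan_to_num(np.asarray(z_map, dtype=float), nan=-np.inf)
    supra = z > threshold_z
    labels, n_lab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters: list[Cluster] = []
    for lab in range(1, n_lab + 1):
        where = labels == lab
        size = int(where.sum())
        flat = np.where(where.ravel(), z.ravel(), -np.inf)
        peak_flat = int(np.argmax(flat))  # argmax returns the first (lowest index) max
        peak = np.unravel_index(peak_flat, z.shape)
        world = half_grid_world(grid, peak) if grid is not None else (
            float(peak[0]), float(peak[1]), float(peak[2]))
        clusters.append(
            Cluster(
                size_voxels=size,
                peak_z=float(z[peak]),
                peak_voxel=tuple(int(i) for i in peak),
                peak_world_mm=world,
                voxels=np.argwhere(where) if keep_voxels else None,
            )
        )
    return clusters


def _ec_density_3d(z: float) -> float:
    """3D Gaussian-field Euler characteristic density at threshold z (per resel)."""
    return (
        (4.0 * np.log(2.0)) ** 1.5
        / (2.0 * np.pi) ** 2
        * (z * z - 1.0)
        * np.exp(-z * z / 2.0)
    )


def grf_cluster_p(
    cluster_size: int,
    threshold_z: float,
    residual_fwhm_mm: np.ndarray | tuple[float, float, float],
    n_mask_voxels: int,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> float:
    """Family-wise corrected p for a cluster of the given extent (voxels).

    Standard Gaussian random-field cluster-extent correction: the number of
    clusters is Poisson with mean ``E[m]`` (EC density at the threshold times
    the resel count), extents follow ``P(n >= k) = exp(-beta k^{2/3})`` with
    ``beta`` fixed by the expected cluster size, and
    ``p = 1 - exp(-E[m] P(n >= k))``.  FWHM estimates below the voxel size
    are clamped (the resel count would otherwise explode).
    """
    if cluster_size <= 0:
        return 1.0
    fwhm = np.maximum(np.asarray(residual_fwhm_mm, dtype=float),
                      np.asarray(voxel_size_mm, dtype=float))
    resels_per_voxel = float(
        np.prod(np.asarray(voxel_size_mm, dtype=float) / fwhm)
    )
    resels = n_mask_voxels * resels_per_voxel
    e_m = max(resels * _ec_density_3d(threshold_z), 1e-300)
    e_n_voxels = n_mask_voxels * stats.norm.sf(threshold_z) / e_m
    if e_n_voxels <= 0:
        return 1.0
    beta = (_GAMMA_5_2 / e_n_voxels) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * float(cluster_size) ** (2.0 / 3.0))
    p = 1.0 - np.exp(-e_m * p_extent)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def whole_brain_clusters(
    result: GLMResult,
    threshold_z: float = 3.09,
    alpha: float = 0.05,
    connectivity: int = 26,
    two_sided: bool = True,
) -> ClusterReport:
    """Cluster-level GRF correction of a GLM Z map, both signs analysed.

    The cluster correction is one-sided per map; the positive map and (when
    ``two_sided``) its negation are thresholded separately and each cluster
    is tagged with its direction.  Clusters are sorted by corrected p.
    """
    clusters: list[Cluster] = []
    directions = [("positive", result.z_map)]
    if two_sided:
        directions.append(("negative", -result.z_map))
    for direction, zm in directions:
        for c in extract_clusters(zm, threshold_z, connectivity, result.grid,
                                  keep_voxels=True):
            c.direction = direction
            c.grf_p = grf_cluster_p(
                c.size_voxels, threshold_z, result.residual_fwhm_mm,
                result.n_mask_voxels, result.grid.voxel_size_mm,
            )
            clusters.append(c)
    clusters.sort(key=lambda c: (c.grf_p, -c.size_voxels))
    return ClusterReport(
        clusters=clusters, threshold_z=threshold_z, alpha=alpha,
        n_mask_voxels=result.n_mask_voxels,
        residual_fwhm_mm=result.residual_fwhm_mm,
    )


@dataclass
class RoiResult:
    """Cluster analysis restricted to one region of interest."""

    region_name: str
    clusters: list[Cluster]
    bonferroni_alpha: float
    n_roi_voxels: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.grf_p < self.bonferroni_alpha]


def roi_analysis(
    result: GLMResult,
    roi_masks: dict[str, np.ndarray],
    loose_threshold_z: float = 2.58,
    alpha: float = 0.05,
    connectivity: int = 26,
    two_sided: bool = True,
) -> list[RoiResult]:
    """Small-volume cluster analysis within candidate regions, Bonferroni corrected.

    Each ROI mask (half-grid) is its own search volume for the GRF
    correction; significance requires ``p < alpha / n_regions``.
    """
    n_regions = len(roi_masks)
    if n_regions == 0:
        raise ValueError("no ROI masks supplied")
    bonf = alpha / n_regions
    out: list[RoiResult] = []
    for name, roi in roi_masks.items():
        if roi.shape != result.z_map.shape:
            # accept full-grid masks by taking the left half
            half = roi.shape[0] // 2
            if roi.shape[0] == 2 * result.z_map.shape[0]:
                roi = roi[:half]
            else:
                raise ValueError(f"ROI {name!r} shape mismatch")
        roi = roi & result.mask
        if roi.sum() == 0:
            raise ValueError(f"ROI {name!r} is empty within the analysis mask")
        clusters: list[Cluster] = []
        directions = [("positive", result.z_map)]
        if two_sided:
            directions.append(("negative", -result.z_map))
        for direction, zm in directions:
            zroi = np.where(roi, zm, np.nan)
            for c in extract_clusters(zroi, loose_threshold_z, connectivity,
                                      result.grid, keep_voxels=True):
                c.direction = direction
                c.grf_p = grf_cluster_p(
                    c.size_voxels, loose_threshold_z, result.residual_fwhm_mm,
                    int(roi.sum()), result.grid.voxel_size_mm,
                )
                c.label = name
                clusters.append(c)
        clusters.sort(key=lambda c: (c.grf_p, -c.size_voxels))
        out.append(RoiResult(region_name=name, clusters=clusters,
                             bonferroni_alpha=bonf, n_roi_voxels=int(roi.sum())))
    return out


@dataclass
class PeakCorrelations:
    """Post-hoc Pearson correlations of LI with AI and unilateral volumes at a peak."""

    peak_voxel: tuple[int, int, int]
    r_ai: float
    p_ai: float
    r_left: float
    p_left: float
    r_right: float
    p_right: float


def peak_posthoc(
    peak: tuple[int, int, int],
    smoothed_volumes: np.ndarray,
    ai_stack: np.ndarray,
    li: np.ndarray,
    grid: TemplateGrid,
) -> PeakCorrelations:
    """Hemisphere-wise decomposition of an asymmetry association at a peak.

    Correlates the laterality index with (a) the asymmetry index at the peak,
    (b) the left-hemisphere smoothed volume there, and (c) the mirrored
    right-hemisphere volume, all two-sided Pearson.  Identifies which
    hemisphere drives an asymmetry-laterality association.
    """
    li = np.asarray(li, dtype=float)
    lefts = np.empty(len(li))
    rights = np.empty(len(li))
    for s in range(len(li)):
        lefts[s], rights[s] = hemisphere_values_at(smoothed_volumes[s], grid, peak)
    ai_vals = np.asarray(ai_stack, dtype=float)[:, peak[0], peak[1], peak[2]]
    out = {}
    for name, vals in (("ai", ai_vals), ("left", lefts), ("right", rights)):
        if np.std(vals) == 0 or np.std(li) == 0:
            out[f"r_{name}"], out[f"p_{name}"] = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(vals, li)
            out[f"r_{name}"], out[f"p_{name}"] = float(r), float(p)
    return PeakCorrelations(peak_voxel=tuple(int(i) for i in peak), **out)


def compare_maps(
    z_map_a: np.ndarray, z_map_b: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Voxel-wise Pearson correlation of two statistical maps within a mask.

    Used for sensitivity analyses (e.g. refitting after excluding a subject
    subset and checking the maps agree).  Returns ``(r, p)``.
    """
    if z_map_a.shape != z_map_b.shape or z_map_a.shape != mask.shape:
        raise ValueError("map/mask shape mismatch")
    a = np.asarray(z_map_a, dtype=float)[mask]
    b = np.asarray(z_map_b, dtype=float)[mask]
    ok = np.isfinite(a) & np.isfinite(b)
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)
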