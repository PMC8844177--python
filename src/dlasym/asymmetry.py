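"""Symmetric template construction, smoothing, and voxel-wise asymmetry maps.

Works on volumes already resampled to a left-right symmetric RAS grid
(:class:`~dlasym.simulate.TemplateGrid`): world ``x = 0`` lies on the
midsagittal plane, voxel index 0 is the leftmost column, and flipping the
x index maps each voxel onto its contralateral homologue.  The asymmetry
index at a left-hemisphere voxel with value ``L`` and mirrored right value
``R`` is

    AI = (L - R) / ((L + R) / 2)

which is bounded in [-2, 2] for non-negative volumes, positive for leftward
asymmetry, and invariant to global intensity scaling.  AI maps are stored on
the left half-grid (one value per left-right voxel pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulate import TemplateGrid

__all__ = [
    "AsymmetryImage",
    "fwhm_from_sigma",
    "sigma_from_fwhm",
    "flip_x",
    "build_symmetric_template",
    "smooth",
    "compute_ai_map",
    "default_ai_floor",
    "hemisphere_values_at",
    "load_volume",
    "save_volume",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def fwhm_from_sigma(sigma_mm: float) -> float:
    """Full-width at half-maximum of a Gaussian with the given sigma (mm)."""
    return _FWHM_PER_SIGMA * sigma_mm


def sigma_from_fwhm(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_PER_SIGMA


def flip_x(data: np.ndarray) -> np.ndarray:
    """Mirror a volume about the midsagittal plane: voxel (i,j,k) -> (X-1-i,j,k).

    On a symmetric grid (even X, world x=0 between the central columns) this
    realises the world-coordinate mirror x -> -x, so no affine change is
    needed when the grid itself is symmetric.
    """
    if data.shape[0] % 2 != 0:
        raise ValueError("x dimension must be even (no declared midline plane)")
    return np.flip(data, axis=0)


def build_symmetric_template(volumes: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Mean of all input volumes and their x-flips; exactly mirror-symmetric.

    Computed as ``(m + flip(m)) / 2`` with ``m`` the plain mean, which equals
    the mean over inputs and flips and is bitwise symmetric (floating-point
    addition is commutative).
    """
    vols = np.asarray(volumes, dtype=np.float64)
    if vols.ndim == 3:
        vols = vols[None]
    if vols.shape[0] == 0:
        raise ValueError("cannot build a template from an empty image list")
    m = vols.mean(axis=0)
    return 0.5 * (m + flip_x(m))


def smooth(data: np.ndarray, grid: TemplateGrid, sigma_mm: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with sigma given in millimetres.

    The kernel sigma is converted to voxel units per axis; boundary handling
    is zero-padding, so only edge voxels lose mass.  Accepts a 3D volume or a
    4D (subject, x, y, z) stack.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / v for v in grid.voxel_size_mm]
    if data.ndim == 4:
        sigma_vox = [0.0, *sigma_vox]
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    return gaussian_filter(data, sigma=sigma_vox, mode="constant")


@dataclass
class AsymmetryImage:
    """Voxel-wise asymmetry-index map on the left half-grid.

    ``data`` has shape ``(X/2, Y, Z)``; ``data[i]`` pairs full-grid left
    column ``i`` with right column ``X-1-i``.  ``valid_mask`` flags voxels
    where the denominator cleared the floor.
    """

    data: np.ndarray
    valid_mask: np.ndarray
    grid: TemplateGrid
    floor: float = 0.0


def default_ai_floor(template: np.ndarray, mask: np.ndarray | None = None,
                     fraction: float = 0.10) -> float:
    """Denominator floor: a fraction of the template's mean grey-matter value.

    Voxel pairs whose mean value falls below this are treated as background
    and flagged invalid; the asymmetry ratio is unstable there.
    """
    vals = template[mask] if mask is not None else template
    return fraction * float(vals.mean())


def compute_ai_map(
    data: np.ndarray, grid: TemplateGrid, floor: float = 0.0
) -> AsymmetryImage:
    """Asymmetry index (L - R) / ((L + R) / 2) per left-right voxel pair.

    Pairs with mean value ``(L + R)/2`` below ``floor`` (or exactly zero) are
    flagged invalid and set to 0.
    """
    if data.shape != grid.shape:
        raise ValueError("volume shape does not match grid")
    half = grid.shape[0] // 2
    left = np.asarray(data[:half], dtype=np.float64)
    right = np.asarray(np.flip(data, axis=0)[:half], dtype=np.float64)
    denom = 0.5 * (left + right)
    valid = denom > max(floor, 0.0)
    ai = np.zeros_like(denom)
    np.divide(left - right, denom, out=ai, where=valid)
    return AsymmetryImage(data=ai, valid_mask=valid, grid=grid, floor=floor)


def hemisphere_values_at(
    data: np.ndarray, grid: TemplateGrid, peak: tuple[int, int, int]
) -> tuple[float, float]:
    """Left and mirrored-right volume values at a half-grid peak coordinate."""
    half = grid.shape[0] // 2
    i, j, k = peak
    if not (0 <= i < half and 0 <= j < grid.shape[1] and 0 <= k < grid.shape[2]):
        raise ValueError(f"peak {peak} outside the left half-grid")
    left = float(data[i, j, k])
    right = float(data[grid.shape[0] - 1 - i, j, k])
    return left, right


def half_grid_world(grid: TemplateGrid, peak: tuple[int, int, int]) -> tuple[float, float, float]:
    """World (mm) coordinate of a left half-grid voxel."""
    xw, yw, zw = grid.world_coords()
    return float(xw[peak[0]]), float(yw[peak[1]]), float(zw[peak[2]])


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_volume(data: np.ndarray, grid: TemplateGrid, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine),
             str(path))
    return path
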