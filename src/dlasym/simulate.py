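"""Synthetic study generator: behaviour, covariates, and grey-matter volumes.

Generates complete synthetic studies — trial-level dichotic-listening
responses, subject covariates, and 3D grey-matter volumes on a left-right
symmetric template grid with planted asymmetry-laterality associations — so
the whole analysis pipeline can be exercised and validated without access to
restricted cohort data.

Behavioural model
-----------------
Each subject carries a latent ear-advantage parameter ``d`` in [-1, 1]; on an
equal-VOT dichotic trial answered correctly, the right-ear syllable is
reported with probability ``(1 + d) / 2``.  The population distribution of
``d`` is a mixture of a point mass at 0 (subjects with no lateralised
advantage) and a Gaussian, with a per-trial lapse (no response) and an
imperfect identification rate.  The mixture parameters are calibrated so the
*realized* trial-level laterality index reproduces the target cohort moments
(defaults: mean 19.6, SD 35.1, ~23% negative, ~11% exactly zero) — most of
the realized LI variance is binomial trial noise from the 12 equal-VOT
presentations, as in real short dichotic protocols.  On mixed-VOT (LS/SL)
trials, correct reports name the short-VOT syllable with high probability
regardless of ear, reproducing the known short-VOT dominance.

Volume model
------------
Each subject's grey-matter volume is a smooth, mirror-symmetric population
pattern modulated by (i) a spatially smooth subject-specific Gaussian noise
field, (ii) bilateral nuisance shifts for scanner, age and sex (bilateral so
the asymmetry-index denominator cancels them), and (iii) planted hemispheric
perturbations proportional to the subject's laterality index at chosen loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dichotic import LONG_VOT, SHORT_VOT, SYLLABLES, build_stimulus_set

__all__ = [
    "CohortSpec",
    "TemplateGrid",
    "PlantedEffect",
    "SimulatedStudy",
    "simulate_li",
    "simulate_behaviour",
    "simulate_covariates",
    "simulate_volumes",
    "make_roi_masks",
    "write_study",
]

# Latent-mixture reference point, calibrated by simulation so that the
# realized LI distribution hits the reference targets below.
_REF_TARGETS = (19.6, 35.1, 0.11)  # mean, sd, prob of exact zero
_REF_LATENT = (0.215, 0.06, 0.09)  # mu_d, sd_d, point mass at d=0

_SCANNERS = ("avanto", "sonata", "trio", "skyra", "prisma", "prisma_fit")
_SCANNER_COUNTS_REF = (66, 14, 109, 46, 30, 16)  # sums to 281


@dataclass(frozen=True)
class CohortSpec:
    """Target cohort composition and behavioural response-model parameters.

    The demographic defaults describe the emulated cohort: 281 adults, 180
    female, mean age 25.7 (SD 10.6) years at scanning, six MRI scanners with
    fixed participant counts, and a mean gap of 5.8 (SD 3.7) years between
    scanning and the listening task.  ``li_mean``/``li_sd``/``prob_zero_li``
    are targets for the realized laterality-index distribution.
    """

    n_subjects: int = 281
    li_mean: float = 19.6
    li_sd: float = 35.1
    prob_zero_li: float = 0.11
    age_mean: float = 25.7
    age_sd: float = 10.6
    n_female: int | None = None  # default: 180/281 of the cohort
    scanner_counts: dict[str, int] | None = None  # default: reference counts
    gap_mean: float = 5.8
    gap_sd: float = 3.7
    n_left_handed: int | None = None  # default: 10/281 of the cohort
    # response-model knobs (calibration parameters, not cohort facts)
    lapse: float = 0.03
    p_correct_eq: float = 0.753
    p_correct_mix: float = 0.85
    p_correct_hom: float = 0.85
    p_short_dominance: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.prob_zero_li <= 1.0):
            raise ValueError("prob_zero_li must lie in [0, 1]")
        for name in ("li_sd", "age_sd", "gap_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("lapse", "p_correct_eq", "p_correct_mix", "p_correct_hom",
                     "p_short_dominance"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def resolved_scanner_counts(self) -> dict[str, int]:
        if self.scanner_counts is not None:
            counts = dict(self.scanner_counts)
            if sum(counts.values()) != self.n_subjects:
                raise ValueError("scanner_counts must sum to n_subjects")
            return counts
        # largest-remainder allocation of the reference proportions
        total_ref = sum(_SCANNER_COUNTS_REF)
        raw = [self.n_subjects * c / total_ref for c in _SCANNER_COUNTS_REF]
        counts = [int(np.floor(r)) for r in raw]
        order = np.argsort([c - r for c, r in zip(counts, raw)])
        for i in order[: self.n_subjects - sum(counts)]:
            counts[i] += 1
        return dict(zip(_SCANNERS, counts))

    def resolved_n_female(self) -> int:
        if self.n_female is not None:
            return self.n_female
        return int(round(self.n_subjects * 180 / 281))

    def resolved_n_left_handed(self) -> int:
        if self.n_left_handed is not None:
            return self.n_left_handed
        return int(round(self.n_subjects * 10 / 281))


def _latent_params(spec: CohortSpec) -> tuple[float, float, float]:
    """Scale the calibrated latent mixture to the spec's LI targets."""
    mu_ref, sd_ref, pi_ref = _REF_LATENT
    mean_ref, sd_t_ref, pz_ref = _REF_TARGETS
    mu = mu_ref * spec.li_mean / mean_ref
    sd = sd_ref * spec.li_sd / sd_t_ref
    pi0 = pi_ref * spec.prob_zero_li / pz_ref
    return mu, sd, min(pi0, 1.0)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def _draw_latent(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    mu, sd, pi0 = _latent_params(spec)
    d = rng.normal(mu, sd, spec.n_subjects)
    d[rng.random(spec.n_subjects) < pi0] = 0.0
    return np.clip(d, -0.95, 0.95)


def simulate_li(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw latent advantages and realized equal-VOT trial outcomes, vectorised.

    Returns a per-subject frame with the latent advantage ``d``, the counts of
    correct right- and left-ear reports over the 12 equal-VOT dichotic trials,
    and the realized laterality index ``li`` (NaN when no correct response).
    This is the exact generative core that :func:`simulate_behaviour`
    materialises into a trial table.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    d = _draw_latent(spec, rng)
    q = (1.0 - spec.lapse) * spec.p_correct_eq
    if spec.li_sd == 0 and spec.lapse == 0:
        # degenerate spec: deterministic responder realising li_mean exactly
        m = np.full(n, 12)
        n_right = np.full(n, int(round(12 * (1 + spec.li_mean / 100.0) / 2)))
    else:
        m = rng.binomial(12, q, n)
        n_right = rng.binomial(m, 0.5 * (1.0 + d))
    n_left = m - n_right
    with np.errstate(invalid="ignore"):
        li = np.where(m > 0, 100.0 * (n_right - n_left) / np.maximum(m, 1), np.nan)
    return pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "latent_advantage": d,
            "n_correct_right": n_right,
            "n_correct_left": n_left,
            "li": li,
        }
    )


def simulate_behaviour(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full trial table consistent with the drawn latent advantages.

    Returns ``(trials, setup, truth)``: one trial row per presentation of the
    36-pair stimulus set per subject; per-subject setup-question answers (all
    passing — setup failures are a recruitment filter, not a modelled
    process); and the ground-truth frame from :func:`simulate_li` (latent
    advantage and realized LI).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = simulate_li(spec, rng)
    pairs = build_stimulus_set()
    eq_pairs = [p for p in pairs if p.vot_category in ("LL", "SS")]
    mix_pairs = [p for p in pairs if p.vot_category in ("LS", "SL")]
    hom_pairs = [p for p in pairs if p.is_homonym]
    deterministic = spec.li_sd == 0 and spec.lapse == 0

    rows: list[tuple] = []
    for s in range(spec.n_subjects):
        sid = truth.at[s, "subject_id"]
        n_right = int(truth.at[s, "n_correct_right"])
        n_left = int(truth.at[s, "n_correct_left"])
        d = truth.at[s, "latent_advantage"]
        # assign the realized right/left-correct counts to the 12 equal-VOT
        # trials; remaining equal-VOT trials are lapses or wrong syllables
        outcome = np.array(
            ["R"] * n_right + ["L"] * n_left + ["X"] * (12 - n_right - n_left)
        )
        if not deterministic:
            rng.shuffle(outcome)
        responses: dict[tuple[str, str], str] = {}
        for p, o in zip(eq_pairs, outcome):
            if o == "R":
                resp = p.right_syllable
            elif o == "L":
                resp = p.left_syllable
            else:
                if spec.lapse > 0 and rng.random() < spec.lapse / (
                    spec.lapse + (1 - spec.lapse) * (1 - spec.p_correct_eq)
                ):
                    resp = ""
                else:
                    others = [x for x in SYLLABLES
                              if x not in (p.left_syllable, p.right_syllable)]
                    resp = others[rng.integers(len(others))]
            responses[(p.left_syllable, p.right_syllable)] = resp
        for p in mix_pairs:
            if (not deterministic) and rng.random() < spec.lapse:
                resp = ""
            elif deterministic or rng.random() < spec.p_correct_mix:
                short = p.short_vot_member
                long_ = (p.left_syllable if p.right_syllable == short
                         else p.right_syllable)
                if deterministic or rng.random() < spec.p_short_dominance:
                    resp = short
                else:
                    resp = long_
            else:
                others = [x for x in SYLLABLES
                          if x not in (p.left_syllable, p.right_syllable)]
                resp = others[rng.integers(len(others))]
            responses[(p.left_syllable, p.right_syllable)] = resp
        for p in hom_pairs:
            if (not deterministic) and rng.random() < spec.lapse:
                resp = ""
            elif deterministic or rng.random() < spec.p_correct_hom:
                resp = p.left_syllable
            else:
                others = [x for x in SYLLABLES if x != p.left_syllable]
                resp = others[rng.integers(len(others))]
            responses[(p.left_syllable, p.right_syllable)] = resp
        for idx, p in enumerate(pairs):
            rows.append(
                (sid, idx, p.left_syllable, p.right_syllable,
                 responses[(p.left_syllable, p.right_syllable)])
            )
        _ = d  # latent advantage recorded in truth

    trials = pd.DataFrame(
        rows,
        columns=["subject_id", "trial_index", "left_syllable",
                 "right_syllable", "response"],
    )
    setup = pd.DataFrame(
        {
            "subject_id": truth["subject_id"],
            "q1": "left",
            "q2": "right",
            "q3": "both",
            "q4_slider": 50,
        }
    )
    return trials, setup, truth


def simulate_covariates(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-subject covariates: age at scan, sex, scanner, scan-task gap, handedness."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_subjects
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 70.0)
    gap = np.clip(rng.normal(spec.gap_mean, spec.gap_sd, n), 0.13, 15.3)
    sex = np.zeros(n, dtype=int)  # 0 = male, 1 = female
    sex[rng.permutation(n)[: spec.resolved_n_female()]] = 1
    counts = spec.resolved_scanner_counts()
    scanner = np.repeat(list(counts.keys()), list(counts.values()))
    scanner = scanner[rng.permutation(n)]
    hand = np.full(n, "right", dtype=object)
    hand[rng.permutation(n)[: spec.resolved_n_left_handed()]] = "left"
    return pd.DataFrame(
        {
            "subject_id": _subject_ids(n),
            "age_at_scan": age,
            "sex": sex,
            "scanner": scanner,
            "years_elapsed": gap,
            "handedness": hand,
        }
    )


@dataclass(frozen=True)
class TemplateGrid:
    """A left-right symmetric RAS sampling grid.

    The x-dimension is even and world ``x = 0`` falls on the midsagittal
    plane between the two central voxel columns, so flipping the voxel index
    ``i -> X-1-i`` maps each voxel onto its mirror.  Voxel index 0 is the
    leftmost (most negative world x); left-hemisphere voxels occupy indices
    ``0 .. X/2 - 1``.
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self):
        if self.shape[0] % 2 != 0:
            raise ValueError("x dimension must be even (midsagittal symmetry)")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        for ax in range(3):
            a[ax, ax] = self.voxel_size_mm[ax]
            a[ax, 3] = -(self.shape[ax] - 1) / 2.0 * self.voxel_size_mm[ax]
        return a

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Axis-aligned world coordinate vectors (mm) for the three axes."""
        return tuple(
            (np.arange(self.shape[ax]) - (self.shape[ax] - 1) / 2.0)
            * self.voxel_size_mm[ax]
            for ax in range(3)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass(frozen=True)
class PlantedEffect:
    """A localised asymmetry-laterality association to plant in the volumes.

    ``beta`` is the asymmetry-index slope per laterality-index percentage
    point at the effect centre.  ``hemisphere_mode`` selects which hemisphere
    carries the volume change: ``left_driven`` (left volume grows with LI),
    ``right_driven`` (right volume shrinks with LI — the pattern where larger
    right-sided volume accompanies atypical left-ear advantage), or ``both``.
    """

    center_voxel: tuple[int, int, int]  # left-hemisphere voxel index
    radius_mm: float
    beta: float
    hemisphere_mode: str = "right_driven"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.hemisphere_mode not in ("left_driven", "right_driven", "both"):
            raise ValueError(f"unknown hemisphere_mode: {self.hemisphere_mode}")


@dataclass
class SimulatedStudy:
    """Volumes and ground truth for one synthetic study."""

    volumes: np.ndarray  # (n_subjects, X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool, mirror-symmetric
    baseline: np.ndarray  # (X, Y, Z) population pattern
    grid: TemplateGrid
    effects: list[PlantedEffect]
    li: np.ndarray
    subject_ids: list[str]


def baseline_pattern(grid: TemplateGrid) -> np.ndarray:
    """Smooth mirror-symmetric population grey-matter pattern (ellipsoidal)."""
    xw, yw, zw = grid.world_coords()
    x2 = (xw / 55.0) ** 2
    y2 = (yw / 70.0) ** 2
    z2 = (zw / 55.0) ** 2
    r2 = x2[:, None, None] + y2[None, :, None] + z2[None, None, :]
    return 0.75 * np.exp(-1.5 * r2)


def grey_matter_mask(grid: TemplateGrid, threshold: float = 0.15) -> np.ndarray:
    return baseline_pattern(grid) > threshold


def _effect_weight(grid: TemplateGrid, effect: PlantedEffect) -> np.ndarray:
    """Gaussian radial weight of a planted effect around its (left) centre."""
    xw, yw, zw = grid.world_coords()
    cx, cy, cz = effect.center_voxel
    d2 = (
        (xw - xw[cx])[:, None, None] ** 2
        + (yw - yw[cy])[None, :, None] ** 2
        + (zw - zw[cz])[None, None, :] ** 2
    )
    s = effect.radius_mm / 2.0
    w = np.exp(-d2 / (2.0 * s * s))
    w[w < 0.05] = 0.0
    return w


def simulate_volumes(
    spec: CohortSpec,
    grid: TemplateGrid,
    effects: list[PlantedEffect],
    li: np.ndarray,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.06,
    noise_fwhm_mm: float = 8.0,
    scanner_amplitude: float = 0.04,
    dtype=np.float32,
) -> SimulatedStudy:
    """Generate per-subject grey-matter volumes with planted asymmetry effects.

    Each volume is ``baseline * (1 + noise + nuisance +/- planted term)``,
    clipped at zero.  The subject noise field is white Gaussian noise smoothed
    to ``noise_fwhm_mm`` and rescaled to standard deviation ``noise_sd``
    (relative units).  Nuisance shifts (scanner, age, sex) are bilateral, so
    they largely cancel in the asymmetry index.  Planted effects perturb one
    or both hemispheres in proportion to the subject's laterality index so the
    local asymmetry-index slope equals ``effect.beta`` at the effect centre.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    li = np.asarray(li, dtype=float)
    n = len(li)
    if np.any(np.isnan(li)):
        raise ValueError("li contains NaN; exclude undefined subjects first")
    base = baseline_pattern(grid)
    mask = base > 0.15
    half = grid.shape[0] // 2

    for eff in effects:
        cx, cy, cz = eff.center_voxel
        if cx >= half:
            raise ValueError("effect centre must be a left-hemisphere voxel")
        mirror = (grid.shape[0] - 1 - cx, cy, cz)
        if not (mask[eff.center_voxel] and mask[mirror]):
            raise ValueError("effect region lies outside the grey-matter mask")

    sigma_vox = [
        noise_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
        for v in grid.voxel_size_mm
    ]
    noise = rng.standard_normal((n, *grid.shape)).astype(dtype)
    noise = gaussian_filter(noise, sigma=[0.0, *sigma_vox], mode="constant")
    noise *= noise_sd / noise[:, mask].std()

    rel = 1.0 + noise  # relative modulation per subject
    del noise

    if covariates is not None:
        scan_levels = {s: i for i, s in enumerate(_SCANNERS)}
        offs = np.array(
            [scan_levels.get(s, 0) for s in covariates["scanner"]], dtype=float
        )
        offs = scanner_amplitude * (offs - offs.mean()) / max(len(_SCANNERS) - 1, 1)
        offs = offs + 0.002 * (
            np.asarray(covariates["age_at_scan"], dtype=float)
            - np.asarray(covariates["age_at_scan"], dtype=float).mean()
        )
        offs = offs + 0.02 * (
            np.asarray(covariates["sex"], dtype=float)
            - np.asarray(covariates["sex"], dtype=float).mean()
        )
        rel += offs[:, None, None, None].astype(dtype)

    for eff in effects:
        w = _effect_weight(grid, eff).astype(dtype)
        term = eff.beta * li[:, None, None, None].astype(dtype)
        wl = w.copy()
        wl[half:] = 0.0  # left-hemisphere part of the weight
        wr = np.flip(wl, axis=0)
        if eff.hemisphere_mode == "left_driven":
            rel += term * wl[None]
        elif eff.hemisphere_mode == "right_driven":
            rel -= term * wr[None]
        else:  # both
            rel += 0.5 * term * wl[None]
            rel -= 0.5 * term * wr[None]

    vols = np.clip(rel * base.astype(dtype)[None], 0.0, None)
    subject_ids = (
        list(covariates["subject_id"]) if covariates is not None
        else _subject_ids(n)
    )
    return SimulatedStudy(
        volumes=vols, mask=mask, baseline=base, grid=grid,
        effects=list(effects), li=li, subject_ids=subject_ids,
    )


def make_roi_masks(
    grid: TemplateGrid, radius_mm: float = 11.0
) -> dict[str, np.ndarray]:
    """Three disjoint synthetic left-hemisphere parcels for ROI analysis.

    Synthetic stand-ins for the three superior-temporal regions of interest
    (Heschl's gyrus, posterior superior temporal gyrus, planum temporale):
    spheres placed anterior-to-posterior along the left temporal region.
    Real atlas masks in the same grid may be substituted via file input.
    """
    xw, yw, zw = grid.world_coords()
    centers = {
        "heschl": (-40.0, -12.0, 4.0),
        "pstg": (-44.0, -34.0, 4.0),
        "planum_temporale": (-42.0, -52.0, 8.0),
    }
    mask = grey_matter_mask(grid)
    half = grid.shape[0] // 2
    out: dict[str, np.ndarray] = {}
    for name, (cx, cy, cz) in centers.items():
        d2 = (
            (xw - cx)[:, None, None] ** 2
            + (yw - cy)[None, :, None] ** 2
            + (zw - cz)[None, None, :] ** 2
        )
        m = (d2 <= radius_mm**2) & mask
        m[half:] = False  # left hemisphere only
        out[name] = m
    # enforce pairwise disjointness deterministically (first named wins)
    claimed = np.zeros(grid.shape, dtype=bool)
    for name in out:
        out[name] = out[name] & ~claimed
        claimed |= out[name]
    return out


def write_study(
    study: SimulatedStudy,
    covariates: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a simulated study to disk: NIfTI volumes, masks, TSVs, ground truth."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    affine = study.grid.affine
    for i, sid in enumerate(study.subject_ids):
        p = outdir / f"{sid}_gm.nii"
        nib.save(nib.Nifti1Image(study.volumes[i].astype(np.float32), affine), p)
        paths[f"volume:{sid}"] = p
    p = outdir / "mask.nii"
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), affine), p)
    paths["mask"] = p
    for name, m in make_roi_masks(study.grid).items():
        p = outdir / f"roi_{name}.nii"
        nib.save(nib.Nifti1Image(m.astype(np.uint8), affine), p)
        paths[f"roi:{name}"] = p
    p = outdir / "covariates.tsv"
    covariates.to_csv(p, sep="\t", index=False)
    paths["covariates"] = p
    p = outdir / "ground_truth.tsv"
    truth.to_csv(p, sep="\t", index=False)
    paths["ground_truth"] = p
    p = outdir / "ground_truth_effects.json"
    with open(p, "w") as fh:
        json.dump(
            [
                {
                    "center_voxel": list(e.center_voxel),
                    "radius_mm": e.radius_mm,
                    "beta": e.beta,
                    "hemisphere_mode": e.hemisphere_mode,
                }
                for e in study.effects
            ],
            fh,
            indent=2,
        )
    paths["effects"] = p
    return paths
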