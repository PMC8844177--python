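# Methods

This note documents the models implemented in `dlasym`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that affect results.

## 1. Dichotic-listening scoring

The stimulus set is the full 6×6 grid of ordered consonant–vowel pairs:
36 presentations, of which 6 are homonyms and 30 dichotic. Pairs are
classified by voice-onset time (VOT): *ba, da, ga* short (S), *ta, ka, pa*
long (L), giving LL (6), SS (6), LS (9, long left / short right) and SL (9).

A response is correct when it names either presented syllable; a missing
response (no answer within the response window) counts as an error. On
homonym trials correctness requires the shared syllable itself — the task
offers all six syllables, and crediting any response would make homonym QC
vacuous. Subject-level exclusions:

* any failed headphone-setup question; the balance slider is accepted on the
  closed interval [30, 70] ("between 30 and 70" read inclusively, tested
  explicitly);
* dichotic error rate **strictly** greater than 0.80, or homonym error rate
  strictly greater than 0.50.

The laterality index uses only the 12 equal-VOT dichotic pairs, because
responses on mixed pairs are dominated by the short-VOT member regardless of
ear (the scoring reports this dominance share per subject rather than
assuming it). A correct response is credited to the ear whose syllable was
named — unambiguous on dichotic trials; homonym trials never enter the LI.
`LI = 100·(nR − nL)/(nR + nL)` is reported in percentage points (the ×100
scaling is what makes cohort means of ~20 with SDs of ~35 meaningful);
subjects with `nR + nL = 0` get an undefined LI and a QC flag.

## 2. Synthetic cohort generator

The generator is the test bed for the whole pipeline; its defaults *are* the
emulated study conditions: 281 subjects, 180 female, age 25.7 ± 10.6 years,
six scanners with counts (66, 14, 109, 46, 30, 16), a 5.8 ± 3.7 year gap
between scan and task, 10 left-handers with no LI association, and a cohort
LI distribution with mean ≈ 19.6, SD ≈ 35.1, ~23% negative and ~11% exactly
zero.

**Behaviour.** Each subject has a latent ear advantage `d ∈ [−1, 1]`; a
correct equal-VOT response names the right-ear syllable with probability
`(1 + d)/2`. `d` is a mixture of a point mass at 0 and a Gaussian. The key
modelling fact is that with only 12 equal-VOT trials, most of the realized
LI variance is binomial trial noise, and exact zeros arise naturally from
the discreteness (`nR = nL`); the explicit point mass tops this up. The
mixture (point mass 0.09, `d ~ N(0.215, 0.06)`) and the per-trial correct
probability (0.73) were calibrated once, by simulation, so the *realized*
LI distribution hits the targets (verified at n = 200 000: mean 19.57,
SD 34.7, 23.1% negative, 10.9% zero) and then frozen. The spec-level knobs
`li_mean`, `li_sd`, `prob_zero_li` scale these latent parameters
proportionally; that mapping is exact at the default operating point and
approximate away from it. A degenerate request (`li_sd = 0` and
`lapse = 0`) switches to a deterministic responder that realises `li_mean`
exactly — a Bernoulli responder cannot produce zero variance. Mixed-VOT
trials name the short-VOT member with probability 0.9 when correct
(accuracy 0.85), homonym accuracy is 0.85, and the lapse (missing-response)
rate is 0.03; these response-rule values are calibration choices, not cohort
facts, and yield the intended category-accuracy ordering (mixed > equal-VOT)
with essentially no QC exclusions.

**Volumes.** Each grey-matter volume is
`baseline · (1 + noise + nuisance ± planted) clipped at 0`, on a 40×48×40
grid at 4 mm isotropic — a desk-scale stand-in for a 2 mm template space.
The baseline is a smooth mirror-symmetric ellipsoidal pattern (mask =
baseline > 0.15, ~15 500 voxels). Subject noise is white Gaussian noise
smoothed to 8 mm FWHM and scaled to SD 0.06 in relative units; 8 mm was
chosen as a realistic residual smoothness for volumetric grey-matter data
(somewhat above the applied 6 mm kernel) and fixed before any calibration
measurements. Scanner, age and sex shifts are *bilateral*, so the AI
denominator cancels them — the same rationale that motivates analysing
asymmetry indices rather than raw volumes. A planted effect perturbs the
left and/or right hemisphere in proportion to the subject's LI with a
Gaussian radial profile (sd = radius/2), scaled so the local AI slope equals
`beta` at the centre; `right_driven` shrinks the right hemisphere as LI
grows (the pattern in which larger right-sided volume accompanies atypical
left-ear advantage).

**What the generator does not emulate:** cortical anatomy and folding,
registration error, Jacobian modulation, multi-site intensity
nonstationarity, spatially varying smoothness, non-Gaussian population
heterogeneity. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline*, not properties of any real cohort.

## 3. Asymmetry maps

The grid is RAS with world x = 0 on the midsagittal plane between the two
central voxel columns (x even), so voxel `i ↦ X−1−i` is the exact mirror;
world x < 0 is the left hemisphere and AI > 0 means leftward asymmetry.
Template construction uses `(mean + flip(mean))/2`, which is bitwise
symmetric. Smoothing is performed in mm (σ/voxel-size per axis) with
zero-padding — only edge voxels are affected, and the analysis mask is
interior. AI is computed **after** smoothing. Voxel pairs whose mean value
falls below a floor — by default 10% of the template's mean grey-matter
value — are flagged invalid: the AI ratio is unstable near empty voxels and
no principled threshold exists upstream, so the floor is a declared
convention recorded in the AI sidecar.

## 4. GLM and cluster inference

Per valid half-grid voxel, ordinary least squares of AI on LI with
intercept, age at scan, years elapsed, sex, and k−1 scanner dummies
(reference coding; the design is rank-checked and offending columns are
named on failure; handedness is deliberately not a covariate — a
subject-subset sensitivity refit is provided instead). Voxels with zero
residual variance (relative tolerance 1e−20 of the data scale) are dropped.
t → Z uses probability matching `z = Φ⁻¹(F_t(t; df))` computed in log-tail
space (`ndtri_exp`), so |Z| beyond 8 does not saturate.

Residual smoothness per axis comes from the variance `v` of spatial first
differences of standardised residuals: `ρ = 1 − v/2`,
`FWHM = D·√(−2 ln 2/ln ρ)` for voxel spacing `D`, clamped below at the voxel
size (the white-noise limit). Clusters are connected components of
`{Z > threshold}` under 26-connectivity (declared in config; 6 and 18 are
available); peaks break ties by lowest linear index. The family-wise cluster
p is the standard Gaussian-random-field extent correction:

```
E[m] = R · (4 ln 2)^{3/2} (2π)^{−2} (z² − 1) e^{−z²/2}
P(n ≥ k) = exp(−β k^{2/3}),  β = (Γ(5/2)/E[n])^{2/3},  E[n] = V·Φ(−z)/E[m]
p = 1 − exp(−E[m] · P(n ≥ k))
```

with `R` the mask volume in resels from the estimated smoothness. Cluster
correction on a Z map is one-sided, so both the map and its negation are
analysed and every cluster is reported with its direction. ROI analysis
reruns the same machinery inside each mask (the ROI as its own search
volume) at the loose threshold Z > 2.58 with Bonferroni α/3. The three
bundled left-temporal ROI masks are synthetic stand-ins placed
anterior-to-posterior along the temporal region; real atlas masks on the
same grid can be substituted through file input.

Post-hoc decomposition correlates LI with the AI, the left volume and the
mirrored right volume at each significant peak (two-sided Pearson);
`compare_maps` gives the voxel-wise Pearson correlation of two Z maps for
sensitivity refits.

## 5. Validation studies and their problem sizes

`dlasym.validation` packages the simulation studies the test suite runs:

* **Null family-wise error:** 400 complete null studies (n = 60, default
  grid) in the test suite, 200 in the acceptance script; a study counts as a
  false positive if any cluster in either direction has GRF p < 0.05.
  Measured rates are ≈ 0.05–0.06, inside the accepted [0.01, 0.09] band.
* **Permutation oracle:** the LI column is exchangeable under the null, so
  permuting it and recording the maximum cluster extent gives an exact
  reference distribution; 3 studies × 2000 permutations are pooled.
* **Planted-effect power:** the effect slope for a target peak Z is derived
  analytically, `beta = z·sd(AI)/(sd(LI)·√n·a)`, where `sd(AI)` is measured
  at the effect centre on a pilot null study and
  `a = (s²/(s² + σ²))^{3/2}` is the peak attenuation of a Gaussian-profile
  effect (sd `s = radius/2`) under the analysis kernel (sd σ). At the
  default target (peak Z ≈ 5, n = 281) the realized mean peak Z is ≈ 5.2.

These sizes keep the full suite around six minutes on one CPU while leaving
the stochastic checks well-powered.

## 6. Known limitations

* **GRF tail conservatism at desk scale.** On the 4 mm grid the residual
  field has FWHM ≈ 2.5 voxels, and the continuum GRF approximation
  overstates cluster p in the deep tail relative to the permutation oracle:
  measured ratios grf/perm are ≈ 1.1–1.8 for p ∈ [0.05, 0.2] but reach
  ≈ 2.3–3 at p ≈ 0.01–0.02 (the lattice merges/hides small clusters, so the
  continuum expected cluster count E[m] ≈ 4.2 versus ≈ 3.0 observed, and the
  `k^{2/3}` extent tail is too heavy). Two consequences are visible in the
  acceptance suite: the deep-tail permutation-agreement check fails at the
  0.01–0.02 levels, and a planted effect with expected peak Z ≈ 5 is
  detected in ~84% rather than ≥90% of replicates (misses sit at
  GRF p ≈ 0.08, which a permutation-calibrated p would place near
  0.04–0.06). The formula was verified to reproduce realistic cluster p
  magnitudes at fine-grid scale (e.g. a 153-voxel cluster on a 2 mm grid at
  plausible smoothness → p ≈ 0.007). Error control itself is conservative,
  never inflated, at all measured levels.
* The upstream VBM steps (brain extraction, segmentation, nonlinear
  registration, modulation) are out of contract: the pipeline starts from
  volumes already in symmetric template space.
* Hemisphere correspondence is exact voxel mirroring on the symmetric grid;
  registration-based correspondence is not modelled.
* Smoothness estimation assumes a stationary Gaussian autocorrelation;
  nonstationary smoothness would bias the resel count.
* The behavioural generator's response-rule parameters are calibration
  knobs; only the realized LI distribution and the category-accuracy
  ordering are matched to cohort-level targets.
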