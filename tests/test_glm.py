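"""Design building, voxel-wise OLS, t->Z, smoothness, clusters, GRF p, post-hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from dlasym import (
    CohortSpec,
    TemplateGrid,
    build_design,
    compare_maps,
    estimate_smoothness,
    extract_clusters,
    fit_voxelwise,
    grf_cluster_p,
    peak_posthoc,
    roi_analysis,
    simulate_covariates,
    t_to_z,
    whole_brain_clusters,
)
from dlasym.simulate import make_roi_masks


def _covariates(n, seed=0, n_scanners=6):
    spec = CohortSpec(n_subjects=n, seed=seed)
    return simulate_covariates(spec)


class TestDesign:
    def test_six_scanners_give_five_dummies_and_df(self):
        cov = _covariates(281)
        li = np.random.default_rng(0).normal(20, 35, 281)
        d = build_design(cov, li)
        assert sum(c.startswith("scanner[") for c in d.columns) == 5
        # intercept + li + age + years + sex + 5 scanner dummies
        assert d.matrix.shape == (281, 10)
        assert d.n - d.matrix.shape[1] == 271  # residual df

    def test_constant_sex_column_rejected(self):
        cov = _covariates(50)
        cov["sex"] = 1
        li = np.arange(50, dtype=float)
        with pytest.raises(ValueError, match="sex"):
            build_design(cov, li)

    def test_missing_covariate_rejected(self):
        cov = _covariates(30)
        cov.loc[3, "age_at_scan"] = np.nan
        with pytest.raises(ValueError, match="age_at_scan"):
            build_design(cov, np.zeros(30))

    def test_li_is_single_effect_column(self):
        cov = _covariates(40)
        d = build_design(cov, np.arange(40, dtype=float))
        assert d.columns[d.li_index] == "li"


class TestVoxelwiseFit:
    def _toy(self, n=40, V=(4, 5, 5), seed=0, noise=1.0):
        rng = np.random.default_rng(seed)
        cov = _covariates(n, seed)
        li = rng.normal(20, 35, n)
        d = build_design(cov, li)
        beta_true = rng.normal(0, 1e-3, V)
        Y = beta_true[None] * li[:, None, None, None]
        Y = Y + noise * 1e-2 * rng.standard_normal((n, *V))
        mask = np.ones(V, dtype=bool)
        return d, li, beta_true, Y, mask

    def test_noiseless_recovery(self):
        d, li, beta_true, Y, mask = self._toy(noise=0.0)
        res = fit_voxelwise(Y, d, mask=mask, keep_residuals=False)
        assert np.allclose(res.beta_map, beta_true, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        """Per-voxel beta/t agree with an independent normal-equations solver."""
        d, li, _, Y, mask = self._toy(seed=3)
        res = fit_voxelwise(Y, d, mask=mask, keep_residuals=False)
        X = d.matrix
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = tuple(rng.integers(0, s) for s in Y.shape[1:])
            y = Y[(slice(None), *v)]
            bh = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bh
            s2 = resid @ resid / (X.shape[0] - X.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[d.li_index, d.li_index])
            assert res.beta_map[v] == pytest.approx(bh[d.li_index], abs=1e-10)
            assert res.t_map[v] == pytest.approx(bh[d.li_index] / se, abs=1e-8)

    def test_sign_equivariance(self):
        d, li, _, Y, mask = self._toy(seed=4)
        a = fit_voxelwise(Y, d, mask=mask, keep_residuals=False)
        b = fit_voxelwise(-Y, d, mask=mask, keep_residuals=False)
        assert np.allclose(b.beta_map, -a.beta_map)
        assert np.allclose(b.t_map[mask], -a.t_map[mask], equal_nan=True)
        assert np.allclose(b.z_map[mask], -a.z_map[mask], equal_nan=True)

    def test_confound_shift_invariance(self):
        """Adding a constant to age is absorbed by the intercept."""
        d, li, _, Y, mask = self._toy(seed=5)
        cov = _covariates(40, 5)
        rng = np.random.default_rng(5)
        li = rng.normal(20, 35, 40)
        d1 = build_design(cov, li)
        cov2 = cov.copy()
        cov2["age_at_scan"] = cov2["age_at_scan"] + 100.0
        d2 = build_design(cov2, li)
        a = fit_voxelwise(Y, d1, mask=mask, keep_residuals=False)
        b = fit_voxelwise(Y, d2, mask=mask, keep_residuals=False)
        assert np.allclose(a.t_map[mask], b.t_map[mask], atol=1e-8)

    def test_zero_variance_voxel_flagged(self):
        d, li, _, Y, mask = self._toy(seed=6)
        Y[:, 0, 0, 0] = 5.0  # constant: zero residual variance
        res = fit_voxelwise(Y, d, mask=mask, keep_residuals=False)
        assert not res.mask[0, 0, 0]
        assert np.isnan(res.t_map[0, 0, 0])

    def test_null_t_rate_at_z_threshold(self):
        """With LI unrelated to the data, |t| exceeding z=3.09-equivalent is ~0.1%."""
        n, V = 60, 20000
        rng = np.random.default_rng(7)
        cov = _covariates(n, 7)
        li = rng.normal(20, 35, n)
        d = build_design(cov, li)
        Y = rng.standard_normal((n, V, 1, 1))
        res = fit_voxelwise(Y, d, mask=np.ones((V, 1, 1), bool),
                            keep_residuals=False)
        rate = (np.abs(res.z_map) > 3.09).mean()
        # two-sided nominal rate 0.002; allow Monte-Carlo slack
        assert 0.0005 < rate < 0.004


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 5) == 0.0
        assert t_to_z(0.0, 500) == 0.0

    def test_normal_limit(self):
        assert t_to_z(1.96, 10**7) == pytest.approx(1.96, abs=1e-3)

    def test_high_precision_oracle(self):
        # value computed with 50-digit arithmetic via the regularised
        # incomplete beta function: P(T_272 > 2.5) = 0.0065042694...
        assert t_to_z(2.5, 272) == pytest.approx(2.4835354419209065, abs=1e-10)

    def test_sign_preserving_and_monotone(self):
        t = np.array([-5.0, -1.0, 0.0, 1.0, 5.0])
        z = t_to_z(t, 30)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(z, -t_to_z(-t, 30))

    def test_extreme_tail_does_not_saturate(self):
        z = t_to_z(50.0, 300)
        assert np.isfinite(z) and z > 8.0


class TestSmoothness:
    def test_white_noise_clamps_to_voxel_size(self):
        rng = np.random.default_rng(0)
        res = rng.standard_normal((20, 16, 16, 16))
        mask = np.ones((16, 16, 16), bool)
        fwhm = estimate_smoothness(res, mask, (4.0, 4.0, 4.0))
        assert np.allclose(fwhm, 4.0, atol=0.5)

    def test_known_kernel_recovered(self):
        """Noise smoothed at 6 mm FWHM is estimated within 15%."""
        rng = np.random.default_rng(1)
        vox = 2.0
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / vox
        res = gaussian_filter(rng.standard_normal((12, 40, 40, 40)),
                              [0, sigma_vox, sigma_vox, sigma_vox])
        mask = np.ones((40, 40, 40), bool)
        fwhm = estimate_smoothness(res, mask, (vox, vox, vox))
        assert np.all(np.abs(fwhm - 6.0) / 6.0 < 0.15)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        res = gaussian_filter(rng.standard_normal((10, 20, 20, 20)), [0, 1, 1, 1])
        mask = np.ones((20, 20, 20), bool)
        a = estimate_smoothness(res, mask, (2.0, 2.0, 2.0))
        b = estimate_smoothness(10.0 * res, mask, (2.0, 2.0, 2.0))
        assert np.allclose(a, b)

    def test_small_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            estimate_smoothness(np.zeros((5, 4, 4, 4)), np.zeros((4, 4, 4), bool),
                                (2, 2, 2))


class TestClusters:
    def test_single_voxel_cluster(self):
        z = np.zeros((6, 6, 6))
        z[2, 2, 2] = 4.0
        cs = extract_clusters(z, 3.09)
        assert len(cs) == 1 and cs[0].size_voxels == 1
        assert cs[0].peak_voxel == (2, 2, 2) and cs[0].peak_z == 4.0

    def test_corner_touch_connectivity(self):
        z = np.zeros((6, 6, 6))
        z[1, 1, 1] = z[2, 2, 2] = 4.0  # touch only at a corner
        assert len(extract_clusters(z, 3.09, connectivity=26)) == 1
        assert len(extract_clusters(z, 3.09, connectivity=6)) == 2

    def test_planted_blob_size_exact(self):
        # fill a connected region of exactly 153 voxels
        z = np.zeros((20, 20, 20))
        flat = []
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    flat.append((i + 5, j + 5, k + 5))
        for v in flat[:153]:
            z[v] = 5.0
        cs = extract_clusters(z, 3.09)
        assert len(cs) == 1 and cs[0].size_voxels == 153

    def test_peak_tie_lowest_linear_index(self):
        z = np.zeros((6, 6, 6))
        z[1, 1, 1] = z[1, 1, 2] = 4.0
        cs = extract_clusters(z, 3.09)
        assert cs[0].peak_voxel == (1, 1, 1)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(np.zeros((4, 4, 4)), 0.0)


class TestGrfClusterP:
    FWHM = np.array([10.0, 10.0, 10.0])

    def test_zero_size_boundary(self):
        assert grf_cluster_p(0, 3.09, self.FWHM, 8000) == 1.0

    def test_monotone_decreasing_in_size(self):
        ps = [grf_cluster_p(k, 3.09, self.FWHM, 8000) for k in range(1, 200, 5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0.0 < p <= 1.0 for p in ps)

    def test_larger_search_volume_larger_p(self):
        p_small = grf_cluster_p(30, 3.09, self.FWHM, 2000)
        p_big = grf_cluster_p(30, 3.09, self.FWHM, 50000)
        assert p_big > p_small

    def test_subvoxel_fwhm_clamped(self):
        p_clamped = grf_cluster_p(10, 3.09, np.array([1.0, 1.0, 1.0]), 8000,
                                  (4.0, 4.0, 4.0))
        p_at_voxel = grf_cluster_p(10, 3.09, np.array([4.0, 4.0, 4.0]), 8000,
                                   (4.0, 4.0, 4.0))
        assert p_clamped == p_at_voxel


class TestRoiAnalysis:
    def test_bonferroni_divisor_three_regions(self, grid, null_study):
        rois = make_roi_masks(grid)
        out = roi_analysis(null_study["result"], rois)
        for rr in out:
            assert rr.bonferroni_alpha == pytest.approx(0.05 / 3)
            assert round(rr.bonferroni_alpha, 3) == 0.017

    def test_zero_map_no_clusters(self, grid):
        res = _zero_result(grid)
        out = roi_analysis(res, make_roi_masks(grid))
        assert all(len(rr.clusters) == 0 for rr in out)

    def test_planted_effect_in_exactly_one_region(self, grid, null_study):
        res = _zero_result(grid)
        rois = make_roi_masks(grid)
        # inflate Z inside the pstg stand-in only
        half_roi = rois["pstg"][: grid.shape[0] // 2]
        res.z_map[half_roi & res.mask] = 4.0
        out = roi_analysis(res, rois)
        sig = {rr.region_name: len(rr.significant) for rr in out}
        assert sig["pstg"] >= 1
        assert sig["heschl"] == 0 and sig["planum_temporale"] == 0

    def test_empty_mask_rejected(self, grid, null_study):
        with pytest.raises(ValueError, match="empty"):
            roi_analysis(null_study["result"],
                         {"void": np.zeros(null_study["result"].z_map.shape, bool)})


def _zero_result(grid):
    from dlasym.glm import GLMResult
    from dlasym.simulate import grey_matter_mask

    half = grid.shape[0] // 2
    mask = grey_matter_mask(grid)[:half]
    shape = (half, *grid.shape[1:])
    return GLMResult(
        beta_map=np.zeros(shape), t_map=np.zeros(shape), z_map=np.zeros(shape),
        mask=mask, df=50, residual_fwhm_mm=np.array([10.0, 10.0, 10.0]),
        n_mask_voxels=int(mask.sum()), grid=grid,
    )


class TestPosthocAndMapComparison:
    def test_left_proportional_gives_r_one(self, grid):
        n = 30
        li = np.linspace(-40, 90, n)
        vols = np.zeros((n, *grid.shape))
        peak = (10, 24, 20)
        vols[:, peak[0], peak[1], peak[2]] = 0.5 + 1e-3 * li
        vols[:, grid.shape[0] - 1 - peak[0], peak[1], peak[2]] = 0.5
        ai = (vols[:, : grid.shape[0] // 2]
              - np.flip(vols, axis=1)[:, : grid.shape[0] // 2])
        pc = peak_posthoc(peak, vols, ai, li, grid)
        assert pc.r_left == pytest.approx(1.0)
        assert np.isnan(pc.r_right)  # right value constant: undefined, flagged

    def test_shuffled_li_null_correlations(self, grid, null_study):
        """Permutation null: |r| of LI with peak values is small on average."""
        rng = np.random.default_rng(0)
        li = null_study["li"]
        n = len(li)
        peak = (10, 24, 20)
        rs = []
        for _ in range(200):
            pc = peak_posthoc(peak, null_study["smoothed"], null_study["ai"],
                              rng.permutation(li), grid)
            rs.append(pc.r_ai)
        # 95th percentile of |r| under the null is ~1.96/sqrt(n)
        q = np.quantile(np.abs(rs), 0.95)
        assert abs(q - 1.96 / np.sqrt(n)) < 0.1

    def test_identical_and_negated_maps(self, null_study):
        z = null_study["result"].z_map
        m = null_study["result"].mask
        assert compare_maps(z, z, m)[0] == pytest.approx(1.0)
        assert compare_maps(z, -z, m)[0] == pytest.approx(-1.0)

    def test_subset_stability_with_strong_effect(self, grid):
        """Dropping 10 subjects barely changes the map when effects are strong."""
        from dlasym.pipeline import analyze_ai_study
        from dlasym.simulate import PlantedEffect, simulate_volumes

        n = 80
        seed = 31
        rng = np.random.default_rng(seed)
        spec = CohortSpec(n_subjects=n, seed=seed)
        li = rng.normal(20, 35, n)
        cov = _covariates(n, seed)
        eff = PlantedEffect((10, 24, 20), radius_mm=14.0, beta=3e-3)
        study = simulate_volumes(spec, grid, [eff], li, covariates=cov, rng=rng)
        full, _, _, valid = analyze_ai_study(study.volumes, grid, study.mask,
                                             cov, li)
        keep = np.ones(n, bool)
        keep[rng.permutation(n)[:10]] = False
        sub, _, _, _ = analyze_ai_study(study.volumes[keep], grid, study.mask,
                                        cov[keep].reset_index(drop=True), li[keep])
        r, _ = compare_maps(full.z_map, sub.z_map, full.mask & sub.mask)
        assert r > 0.8

    def test_mask_mismatch_rejected(self, null_study):
        z = null_study["result"].z_map
        with pytest.raises(ValueError, match="mismatch"):
            compare_maps(z, z, np.ones((2, 2, 2), bool))


class TestWholeBrain:
    def test_null_study_rarely_significant(self, null_study):
        rep = whole_brain_clusters(null_study["result"])
        for c in rep.clusters:
            assert c.peak_z > rep.threshold_z
        assert all(0 < c.grf_p <= 1 for c in rep.clusters)
        ps = [c.grf_p for c in rep.clusters]
        assert ps == sorted(ps)
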