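"""Radiomic features: hand-enumerated examples, brute-force oracle
equivalence, and invariance to everything outside the mask."""

import math

import numpy as np
import pytest

from oracles import glcm_counts, gldm_counts, glrlm_counts, ngtdm_sums

from gradiomics.errors import DataError
from gradiomics.imaging import RadiographSample
from gradiomics.radiomics import (
    FEATURE_CENSUS,
    DiscretizedRoi,
    discretize,
    extract_all,
    feature_names,
    first_order,
    glcm,
    glcm_matrix,
    gldm,
    glrlm,
    ngtdm,
    shape2d,
)
from gradiomics.saliency import SaliencyResult


def _sample(pixels):
    return RadiographSample(id="t", pixels=np.asarray(pixels, float), label=0)


class TestDiscretize:
    def test_three_bins(self):
        roi = discretize(_sample([[0.0, 0.1, 0.2]]), np.ones((1, 3), bool), 0.1)
        assert roi.levels.tolist() == [[1, 2, 3]]
        assert roi.n_levels == 3

    def test_constant_roi_single_level(self):
        roi = discretize(_sample([[0.4, 0.4], [0.4, 0.4]]), np.ones((2, 2), bool), 0.1)
        assert roi.n_levels == 1

    def test_bin_width_larger_than_range(self):
        roi = discretize(_sample([[0.1, 0.3]]), np.ones((1, 2), bool), 0.5)
        assert roi.n_levels == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            discretize(_sample([[0.1, 0.3]]), np.zeros((1, 2), bool), 0.1)


class TestFirstOrder:
    def test_hand_arithmetic_population_convention(self):
        s = _sample([[0.1, 0.2, 0.3]])
        roi = discretize(s, np.ones((1, 3), bool), 0.05)
        f = first_order(roi, s.pixels[roi.mask])
        assert f["fo_mean"] == pytest.approx(0.2)
        assert f["fo_variance"] == pytest.approx(((0.1**2) * 2) / 3)  # population
        assert f["fo_range"] == pytest.approx(0.2)
        assert f["fo_skewness"] == pytest.approx(0.0, abs=1e-9)  # symmetric

    def test_constant_roi_degenerates(self):
        s = _sample(np.full((3, 3), 0.6))
        roi = discretize(s, np.ones((3, 3), bool), 0.1)
        f = first_order(roi, s.pixels[roi.mask])
        assert f["fo_variance"] == 0.0
        assert f["fo_entropy"] == 0.0
        assert f["fo_uniformity"] == 1.0
        assert f["fo_skewness"] == 0.0 and f["fo_kurtosis"] == 0.0


class TestGlcm:
    ROI = DiscretizedRoi(
        levels=np.array([[1, 1], [2, 2]]), mask=np.ones((2, 2), bool),
        n_levels=2, bin_width=0.5,
    )

    def test_horizontal_pairs_symmetric_counts(self):
        m = glcm_matrix(self.ROI, 1, 0)
        assert m.tolist() == [[2, 0], [0, 2]]
        _, feats = glcm(self.ROI, angles=(0,))
        assert feats["glcm_contrast"] == 0.0
        assert feats["glcm_maximum_probability"] == 0.5

    def test_vertical_pairs_cross_level(self):
        m = glcm_matrix(self.ROI, 1, 90)
        assert m.tolist() == [[0, 2], [2, 0]]
        _, feats = glcm(self.ROI, angles=(90,))
        assert feats["glcm_contrast"] == 1.0

    def test_constant_grid_degenerate(self):
        roi = DiscretizedRoi(levels=np.ones((3, 3), int), mask=np.ones((3, 3), bool),
                             n_levels=1, bin_width=0.5)
        _, feats = glcm(roi)
        assert feats["glcm_maximum_probability"] == 1.0
        assert feats["glcm_joint_entropy"] == 0.0
        assert feats["glcm_contrast"] == 0.0
        assert feats["glcm_correlation"] == 1.0  # zero-variance convention


class TestGlrlm:
    def test_run_enumeration_1x3(self):
        roi = DiscretizedRoi(levels=np.array([[1, 1, 2]]), mask=np.ones((1, 3), bool),
                             n_levels=2, bin_width=0.5)
        matrices, feats = glrlm(roi, angles=(0,))
        assert matrices[0].tolist() == [[0, 1], [1, 0]]
        assert feats["glrlm_run_percentage"] == pytest.approx(2 / 3)

    def test_constant_row_long_run_emphasis(self):
        roi = DiscretizedRoi(levels=np.ones((1, 4), int), mask=np.ones((1, 4), bool),
                             n_levels=1, bin_width=0.5)
        _, feats = glrlm(roi, angles=(0,))
        assert feats["glrlm_lre"] == pytest.approx(16.0)  # 4^2 * 1

    def test_all_distinct_short_runs(self):
        roi = DiscretizedRoi(levels=np.array([[1, 2, 3, 4]]), mask=np.ones((1, 4), bool),
                             n_levels=4, bin_width=0.5)
        _, feats = glrlm(roi, angles=(0,))
        assert feats["glrlm_sre"] == 1.0
        assert feats["glrlm_run_percentage"] == 1.0


class TestGldm:
    def test_constant_3x3_dependence_counts(self):
        roi = DiscretizedRoi(levels=np.ones((3, 3), int), mask=np.ones((3, 3), bool),
                             n_levels=1, bin_width=0.5)
        matrix, _ = gldm(roi, alpha=0, distance=1)
        # center has 8 dependent neighbors, edges 5, corners 3
        assert matrix[0, 8] == 1 and matrix[0, 5] == 4 and matrix[0, 3] == 4

    def test_single_pixel_dependence_zero(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        levels = np.where(mask, 1, 0)
        roi = DiscretizedRoi(levels=levels, mask=mask, n_levels=1, bin_width=0.5)
        matrix, _ = gldm(roi)
        assert matrix.shape == (1, 1) and matrix[0, 0] == 1

    def test_alpha_saturation_counts_all_neighbors(self, rng):
        levels = rng.integers(1, 5, size=(4, 4))
        roi = DiscretizedRoi(levels=levels, mask=np.ones((4, 4), bool),
                             n_levels=4, bin_width=0.1)
        saturated, _ = gldm(roi, alpha=10, distance=1)
        constant, _ = gldm(
            DiscretizedRoi(levels=np.ones((4, 4), int), mask=np.ones((4, 4), bool),
                           n_levels=1, bin_width=0.1),
            alpha=0, distance=1,
        )
        # summed over levels, dependence histogram equals the constant-image one
        assert np.array_equal(saturated.sum(axis=0), constant.sum(axis=0))


class TestNgtdm:
    def test_three_pixel_row_enumeration(self):
        roi = DiscretizedRoi(levels=np.array([[1, 2, 1]]), mask=np.ones((1, 3), bool),
                             n_levels=2, bin_width=0.5)
        sums, feats = ngtdm(roi, distance=1)
        assert sums["s"].tolist() == [2.0, 1.0]
        assert feats["ngtdm_coarseness"] == pytest.approx(0.6)
        assert feats["ngtdm_contrast"] == pytest.approx(2 / 9)
        assert feats["ngtdm_complexity"] == pytest.approx(10 / 9)
        assert feats["ngtdm_strength"] == pytest.approx(2 / 3)

    def test_constant_roi_capped_coarseness(self):
        roi = DiscretizedRoi(levels=np.ones((3, 3), int), mask=np.ones((3, 3), bool),
                             n_levels=1, bin_width=0.5)
        _, feats = ngtdm(roi)
        assert feats["ngtdm_contrast"] == 0.0
        assert feats["ngtdm_coarseness"] == 1e6

    def test_single_pixel_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        roi = DiscretizedRoi(levels=np.where(mask, 1, 0), mask=mask, n_levels=1, bin_width=0.5)
        _, feats = ngtdm(roi)
        assert feats["ngtdm_coarseness"] == 1e6


class TestShape2d:
    def test_single_pixel_marching_squares_goldens(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        f = shape2d(mask)
        assert f["shape_mesh_surface"] == pytest.approx(0.5)  # diamond contour
        assert f["shape_perimeter"] == pytest.approx(2 * math.sqrt(2))
        assert f["shape_maximum_diameter"] == pytest.approx(1.0)
        assert f["shape_elongation"] == 1.0

    def test_solid_square_goldens(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True  # 10x10 block
        f = shape2d(mask)
        assert f["shape_pixel_surface"] == 100.0
        assert f["shape_mesh_surface"] == pytest.approx(100 - 0.5)  # corner cuts
        assert f["shape_perimeter"] == pytest.approx(4 * 9 + 2 * math.sqrt(2))
        assert f["shape_elongation"] == pytest.approx(1.0)  # symmetric

    def test_circle_compactness_increases_with_resolution(self):
        """Sphericity of a rasterized disk rises with resolution toward its
        marching-squares asymptote (~0.943; the staircase contour of a hard
        binary disk overestimates the true perimeter by ~6%)."""

        def disk(radius, pad=3):
            side = 2 * (radius + pad) + 1
            rr, cc = np.mgrid[0:side, 0:side]
            return (rr - side // 2) ** 2 + (cc - side // 2) ** 2 <= radius**2

        small = shape2d(disk(8))["shape_sphericity"]
        large = shape2d(disk(40))["shape_sphericity"]
        assert large > small
        assert large == pytest.approx(0.943, abs=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            shape2d(np.zeros((4, 4), bool))


class TestOracleEquivalence:
    """Exhaustive enumeration oracle on random small masked images."""

    @pytest.mark.parametrize("trial_block", range(4))
    def test_texture_matrices_match_brute_force(self, trial_block):
        rng = np.random.default_rng(1000 + trial_block)
        for _ in range(50):
            h, w = rng.integers(2, 9, size=2)
            img = rng.random((h, w))
            mask = rng.random((h, w)) < 0.7
            if not mask.any():
                mask[rng.integers(h), rng.integers(w)] = True
            roi = discretize(_sample(img), mask, bin_width=0.25)
            lv = roi.levels
            for angle in (0, 45, 90, 135):
                assert np.array_equal(glcm_matrix(roi, 1, angle), glcm_counts(lv, mask, 1, angle))
                from gradiomics.radiomics import glrlm_matrix

                assert np.array_equal(glrlm_matrix(roi, angle), glrlm_counts(lv, mask, angle))
            for alpha in (0, 1):
                assert np.array_equal(gldm(roi, alpha, 1)[0], gldm_counts(lv, mask, alpha, 1))
            sums, _ = ngtdm(roi, 1)
            s_ref, n_ref = ngtdm_sums(lv, mask, 1)
            assert np.allclose(sums["s"], s_ref, atol=1e-10)
            assert np.array_equal(sums["n"], n_ref)

    def test_first_order_matches_direct_formulas(self):
        rng = np.random.default_rng(2000)
        for _ in range(50):
            x = rng.random(rng.integers(2, 40))
            s = _sample(x[None, :])
            roi = discretize(s, np.ones((1, len(x)), bool), 0.1)
            f = first_order(roi, x)
            assert abs(f["fo_mean"] - x.mean()) < 1e-12
            assert abs(f["fo_variance"] - x.var()) < 1e-12
            assert abs(f["fo_energy"] - (x**2).sum()) < 1e-12
            if x.var() > 0:
                skew = ((x - x.mean()) ** 3).mean() / x.var() ** 1.5
                assert abs(f["fo_skewness"] - skew) < 1e-10


class TestExtractAll:
    def _saliency(self, shape):
        mask = np.zeros(shape, bool)
        h, w = shape
        mask[h // 4 : 3 * h // 4, w // 4 : 3 * w // 4] = True
        from gradiomics.saliency import mask_qc

        return SaliencyResult(heatmap=mask.astype(float), mask=mask, qc=mask_qc(mask))

    def test_census_is_87_and_stable(self):
        assert FEATURE_CENSUS == 87
        assert len(feature_names()) == 87
        assert len(set(feature_names())) == 87

    def test_reliable_mask_full_vector(self, small_dataset):
        s = small_dataset[0]
        vec = extract_all(s, self._saliency(s.pixels.shape))
        assert vec.reliable_mask
        assert len(vec.values) == FEATURE_CENSUS
        assert np.all(np.isfinite(vec.values))

    def test_unreliable_mask_zero_padded(self, small_dataset):
        s = small_dataset[0]
        tiny = np.zeros(s.pixels.shape, bool)
        tiny[5, 5] = True
        from gradiomics.saliency import mask_qc

        sal = SaliencyResult(heatmap=tiny.astype(float), mask=tiny, qc=mask_qc(tiny))
        vec = extract_all(s, sal)
        assert not vec.reliable_mask
        assert np.all(vec.values == 0.0)
        assert len(vec.values) == FEATURE_CENSUS

    def test_deterministic(self, small_dataset):
        s = small_dataset[1]
        sal = self._saliency(s.pixels.shape)
        a, b = extract_all(s, sal), extract_all(s, sal)
        assert np.array_equal(a.values, b.values)

    def test_invariant_to_pixels_outside_mask(self, small_dataset, rng):
        s = small_dataset[2]
        sal = self._saliency(s.pixels.shape)
        vec = extract_all(s, sal)
        for _ in range(3):
            noisy = s.pixels.copy()
            noisy[~sal.mask] = rng.random((~sal.mask).sum())
            fuzzed = RadiographSample(id=s.id, pixels=noisy, label=s.label)
            assert np.array_equal(extract_all(fuzzed, sal).values, vec.values)

    def test_glcm_transpose_invariance(self, rng):
        """With the symmetric 4-angle set, transposition permutes angles only."""
        img = rng.random((10, 10))
        mask = rng.random((10, 10)) < 0.8
        mask[4:6, 4:6] = True
        roi = discretize(_sample(img), mask, 0.1)
        roi_t = discretize(_sample(img.T), mask.T, 0.1)
        _, f = glcm(roi)
        _, f_t = glcm(roi_t)
        for key in f:
            assert f[key] == pytest.approx(f_t[key], rel=1e-9), key
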