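import math

import numpy as np
import pytest

from conftest import brute_force_glcm, random_quantized_patch
from fmritex.errors import ContractError, FeatureUndefinedError
from fmritex.texture import (
    DIRECTIONS,
    FEATURE_NAMES,
    GLCM,
    compute_features,
    compute_glcm,
    quantize,
    roi_glcms,
    rotation_invariant_features,
)
from fmritex.volumes import ROIPatch


def patch_from(values, inside=None, slice_index=0):
    values = np.asarray(values, float)
    inside = np.ones_like(values, bool) if inside is None else np.asarray(
        inside, bool)
    return ROIPatch(slice_index=slice_index, values=values, inside=inside)


class TestQuantize:
    def test_equal_width_bins(self):
        p = patch_from([[0.0, 10.0], [20.0, 40.0]])
        (q,) = quantize([p], n_levels=4)
        np.testing.assert_array_equal(q.levels, [[1, 2], [3, 4]])
        assert not q.degenerate

    def test_identity_mapping_when_one_value_per_bin(self):
        p = patch_from([np.arange(8.0)])
        (q,) = quantize([p], n_levels=8)
        np.testing.assert_array_equal(q.levels[0], np.arange(1, 9))

    def test_constant_roi_flags_degenerate(self):
        p = patch_from(np.full((3, 3), 7.0))
        (q,) = quantize([p], n_levels=8)
        assert q.degenerate
        assert (q.levels == 1).all()

    def test_range_pooled_across_slices(self):
        # slice 0 spans [0, 10], slice 1 spans [30, 40]: pooled range [0, 40]
        p0 = patch_from([[0.0, 10.0]], slice_index=0)
        p1 = patch_from([[30.0, 40.0]], slice_index=1)
        q0, q1 = quantize([p0, p1], n_levels=4)
        np.testing.assert_array_equal(q0.levels, [[1, 2]])
        np.testing.assert_array_equal(q1.levels, [[4, 4]])

    def test_shift_invariance(self, rng):
        vals = rng.normal(size=(6, 6))
        qa = quantize([patch_from(vals)], n_levels=8)[0]
        qb = quantize([patch_from(vals + 123.4)], n_levels=8)[0]
        np.testing.assert_array_equal(qa.levels, qb.levels)

    def test_bad_inputs(self):
        with pytest.raises(ContractError):
            quantize([patch_from([[1.0, 2.0]])], n_levels=1)
        with pytest.raises(Exception):
            quantize([], n_levels=8)


class TestComputeGLCM:
    def test_hand_enumerated_horizontal_pairs(self):
        (q,) = quantize([patch_from([[1.0, 2.0], [1.0, 2.0]])], n_levels=2)
        g = compute_glcm(q, direction=0)
        expected = np.array([[0.0, 2.0], [2.0, 0.0]])
        np.testing.assert_array_equal(g.matrix, expected)

    def test_constant_patch_all_mass_on_diagonal(self):
        (q,) = quantize([patch_from(np.full((3, 3), 5.0))], n_levels=8)
        for theta in DIRECTIONS:
            g = compute_glcm(q, theta)
            assert g.matrix[0, 0] == g.matrix.sum() > 0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_brute_force_oracle(self, rng, direction):
        for _ in range(25):
            q = random_quantized_patch(rng)
            got = compute_glcm(q, direction).matrix
            want = brute_force_glcm(q.levels, q.inside, q.n_levels, direction)
            np.testing.assert_array_equal(got, want)

    def test_single_pixel_flags_empty(self):
        (q,) = quantize([patch_from([[3.0]])], n_levels=2)
        g = compute_glcm(q, 0)
        assert g.empty and not g.matrix.any()


class TestRoiGLCMs:
    def test_normalized_and_symmetric(self, rng):
        patches = [random_quantized_patch(rng, n_levels=8) for _ in range(3)]
        for g in roi_glcms(patches):
            if not g.empty:
                assert abs(g.matrix.sum() - 1.0) < 1e-12
                np.testing.assert_allclose(g.matrix, g.matrix.T)

    def test_duplicate_slice_leaves_glcm_unchanged(self, rng):
        q = random_quantized_patch(rng, n_levels=4)
        one = roi_glcms([q])
        two = roi_glcms([q, q])
        for a, b in zip(one, two):
            np.testing.assert_allclose(a.matrix, b.matrix)

    def test_counts_accumulate_over_slices(self, rng):
        qs = [random_quantized_patch(rng, n_levels=4) for _ in range(2)]
        for theta_idx, theta in enumerate(DIRECTIONS):
            want = sum(brute_force_glcm(q.levels, q.inside, 4, theta)
                       for q in qs)
            total = want.sum()
            got = roi_glcms(qs)[theta_idx].matrix
            if total:
                np.testing.assert_allclose(got, want / total)

    def test_single_pixel_roi_is_feature_undefined(self):
        (q,) = quantize([patch_from([[3.0]])], n_levels=2)
        with pytest.raises(FeatureUndefinedError):
            roi_glcms([q])


def normalized_glcm(matrix):
    m = np.asarray(matrix, float)
    return GLCM(matrix=m / m.sum(), direction=0, distance=1, normalized=True)


class TestComputeFeatures:
    def test_point_mass_closed_form(self):
        m = np.zeros((4, 4))
        m[1, 1] = 1.0
        f = compute_features(normalized_glcm(m))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["dissimilarity"] == 0.0
        assert f["homogeneity"] == 1.0
        assert f["maximum_probability"] == 1.0
        assert f["correlation"] == 1.0  # degenerate convention

    def test_two_cell_closed_form(self):
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = compute_features(normalized_glcm(m))
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(math.log(2))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["sum_average"] == pytest.approx(3.0)
        assert f["autocorrelation"] == pytest.approx(2.0)

    def test_unnormalized_input_rejected(self):
        g = GLCM(matrix=np.ones((2, 2)), direction=0, distance=1,
                 normalized=False)
        with pytest.raises(ContractError):
            compute_features(g)

    def test_invariant_ranges_on_random_glcms(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            raw = rng.random((n, n))
            raw = raw + raw.T  # symmetric
            f = compute_features(normalized_glcm(raw))
            assert len(f) == 20 and set(f) == set(FEATURE_NAMES)
            assert 0 < f["energy"] <= 1
            assert f["entropy"] >= 0
            assert 0 < f["homogeneity"] <= 1
            assert 0 < f["maximum_probability"] <= 1
            assert f["contrast"] >= 0
            assert f["dissimilarity"] >= 0
            assert -1 <= f["correlation"] <= 1


class TestSkimageCrossCheck:
    """Independent route: skimage's GLCM on full rectangular patches."""

    def test_features_match_graycomatrix_props(self, rng):
        pytest.importorskip("skimage")
        from skimage.feature import graycomatrix, graycoprops

        levels = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        levels[0, 0], levels[0, 1] = 0, 7  # pin the range so the mapping
        # from intensities to bins is the identity, matching skimage's levels
        # skimage's row offset is +sin(theta), ours is -sin(theta); under
        # symmetric counting that swaps the two diagonals
        angle_of = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        for theta, ang in angle_of.items():
            sk = graycomatrix(levels, [1], [ang], levels=8, symmetric=True,
                              normed=True)[:, :, 0, 0]
            q = quantize([patch_from(levels.astype(float))], n_levels=8)[0]
            # identity mapping: integer grid 0..7 maps to levels 1..8
            mine = roi_glcms([q])[list(DIRECTIONS).index(theta)].matrix
            np.testing.assert_allclose(mine, sk, atol=1e-12)
            f = compute_features(GLCM(matrix=mine, direction=theta,
                                      distance=1, normalized=True))
            assert f["contrast"] == pytest.approx(
                graycoprops(sk[:, :, None, None], "contrast")[0, 0])
            assert f["dissimilarity"] == pytest.approx(
                graycoprops(sk[:, :, None, None], "dissimilarity")[0, 0])
            assert f["homogeneity"] == pytest.approx(
                graycoprops(sk[:, :, None, None], "homogeneity")[0, 0])
            assert f["energy"] == pytest.approx(
                graycoprops(sk[:, :, None, None], "ASM")[0, 0])
            assert f["correlation"] == pytest.approx(
                graycoprops(sk[:, :, None, None], "correlation")[0, 0])


class TestRotationInvariance:
    def test_four_identical_glcms_average_to_themselves(self, rng):
        q = random_quantized_patch(rng, n_levels=8)
        g = roi_glcms([q])[0]
        if g.empty:
            pytest.skip("degenerate draw")
        single = compute_features(g)
        avg = rotation_invariant_features([g, g, g, g])
        for name in FEATURE_NAMES:
            assert avg[name] == pytest.approx(single[name])

    def test_90_degree_rotation_preserves_averaged_vector(self, rng):
        for _ in range(20):
            q = random_quantized_patch(rng, n_levels=8)
            rotated = ROIPatch(slice_index=0,
                               values=np.rot90(q.levels.astype(float)),
                               inside=np.rot90(q.inside))
            (qr,) = quantize([rotated], n_levels=8)
            try:
                fa = rotation_invariant_features(roi_glcms([q]))
                fb = rotation_invariant_features(roi_glcms([qr]))
            except FeatureUndefinedError:
                continue
            for name in FEATURE_NAMES:
                assert fa[name] == pytest.approx(fb[name], abs=1e-9)

    def test_all_empty_directions_raise(self):
        empty = GLCM(matrix=np.zeros((2, 2)), direction=0, distance=1,
                     normalized=True, empty=True)
        with pytest.raises(FeatureUndefinedError):
            rotation_invariant_features([empty] * 4)


class TestSmoothnessMonotonicity:
    def test_smoother_fields_are_more_homogeneous_and_autocorrelated(self, rng):
        from scipy.ndimage import gaussian_filter

        def mean_feats(sigma, n=30):
            homog, autoc = [], []
            for _ in range(n):
                g = gaussian_filter(rng.standard_normal((12, 12)), sigma,
                                    mode="wrap")
                (q,) = quantize([patch_from(g)], n_levels=8)
                f = rotation_invariant_features(roi_glcms([q]))
                homog.append(f["homogeneity"])
                autoc.append(f["autocorrelation"])
            return np.mean(homog), np.mean(autoc)

        h_rough, a_rough = mean_feats(0.5)
        h_smooth, a_smooth = mean_feats(2.0)
        assert h_smooth > h_rough
        assert a_smooth > a_rough


class TestPropertyInvariants:
    """Randomized invariants driven by hypothesis."""

    def test_glcm_normalization_symmetry_and_count_parity(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(values=hnp.arrays(np.float64, (6, 6),
                                 elements=st.floats(-100, 100)),
               n_levels=st.integers(2, 8))
        def check(values, n_levels):
            (q,) = quantize([patch_from(values)], n_levels=n_levels)
            glcms = roi_glcms([q])
            for g in glcms:
                if g.empty:
                    continue
                assert abs(g.matrix.sum() - 1.0) < 1e-12
                np.testing.assert_allclose(g.matrix, g.matrix.T, atol=0)
                f = compute_features(g)
                assert 0 < f["energy"] <= 1 + 1e-12
                assert f["entropy"] >= -1e-12
                assert -1 - 1e-9 <= f["correlation"] <= 1 + 1e-9

        check()

    def test_quantize_is_monotone_and_shift_scale_invariant(self):
        from hypothesis import given, settings, strategies as st
        from hypothesis.extra import numpy as hnp

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(values=hnp.arrays(np.float64, (5, 5),
                                 elements=st.floats(-50, 50)),
               shift=st.floats(-1e3, 1e3), scale=st.floats(0.1, 100))
        def check(values, shift, scale):
            (qa,) = quantize([patch_from(values)], n_levels=8)
            (qb,) = quantize([patch_from(values * scale + shift)], n_levels=8)
            if not (qa.degenerate or qb.degenerate):
                np.testing.assert_array_equal(qa.levels, qb.levels)
            # monotone: ordering of intensities never reverses in levels
            v = values.ravel()
            lv = qa.levels.ravel()
            order = np.argsort(v, kind="stable")
            assert np.all(np.diff(lv[order]) >= 0)

        check()
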