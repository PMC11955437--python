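"""Texture features vs independent brute-force oracles on tiny instances."""

import itertools

import numpy as np
import pytest

from habitatmri.texture import (FeatureSpec, binomial_blur, discretize,
                                extract_features, first_order_features,
                                glcm_features, glcm_matrix, gldm_matrix,
                                glrlm_matrix, glszm_matrix, ngtdm_features,
                                ngtdm_matrix, shape_features)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent, per-voxel enumeration)
# ---------------------------------------------------------------------------

def ngtdm_bruteforce(levels, mask):
    """NGTDM contrast by explicit neighbourhood enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    shape = levels.shape
    s = {}
    n = {}
    n_valid = 0
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        neigh = []
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            j = tuple(np.add(idx, off))
            if all(0 <= j[a] < shape[a] for a in range(3)) and mask[j]:
                neigh.append(levels[j])
        if not neigh:
            continue
        n_valid += 1
        lv = int(levels[idx])
        s[lv] = s.get(lv, 0.0) + abs(levels[idx] - np.mean(neigh))
        n[lv] = n.get(lv, 0) + 1
    occ = sorted(n)
    p = {i: n[i] / n_valid for i in occ}
    if len(occ) < 2:
        return 0.0
    left = sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ) \
        / (len(occ) * (len(occ) - 1))
    right = sum(s.values()) / n_valid
    return left * right


def glcm_contrast_bruteforce(levels, mask, offset):
    """Symmetric co-occurrence contrast by explicit pair enumeration."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    shape = levels.shape
    pairs = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        j = tuple(np.add(idx, offset))
        if all(0 <= j[a] < shape[a] for a in range(3)) and mask[j]:
            pairs.append((levels[idx], levels[j]))
            pairs.append((levels[j], levels[idx]))
    return float(np.mean([(a - b) ** 2 for a, b in pairs]))


class TestBinomialBlur:
    def test_constant_volume_unchanged(self):
        v = np.full((5, 5, 5), 3.7)
        np.testing.assert_allclose(binomial_blur(v, 2), v)

    def test_unit_impulse_separable_kernel(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 1.0
        out = binomial_blur(v, 1)
        k = np.array([0.25, 0.5, 0.25])
        expected = k[:, None, None] * k[None, :, None] * k[None, None, :]
        np.testing.assert_allclose(out[1:4, 1:4, 1:4], expected, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_repetitions_compose(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 7, 5))
        r3 = binomial_blur(v, 3)
        composed = binomial_blur(binomial_blur(binomial_blur(v, 1), 1), 1)
        np.testing.assert_allclose(r3, composed, atol=1e-12)


class TestDiscretize:
    def test_two_bins_split(self):
        vals = np.arange(11, dtype=float).reshape(11, 1, 1)
        mask = np.ones_like(vals, bool)
        lv = discretize(vals, mask, n_bins=2)
        expected = np.where(vals <= 5, 1, 2)
        np.testing.assert_array_equal(lv, expected)

    def test_constant_region_is_level_one(self):
        vals = np.full((3, 3, 1), 4.2)
        lv = discretize(vals, np.ones_like(vals, bool), n_bins=8)
        assert (lv == 1).all()

    def test_fixed_bin_width(self):
        vals = np.array([0.0, 24.0, 26.0]).reshape(3, 1, 1)
        lv = discretize(vals, np.ones_like(vals, bool), bin_width=25.0)
        np.testing.assert_array_equal(lv.reshape(-1), [1, 1, 2])


class TestFirstOrder:
    def test_constant_region(self):
        v = np.full((3, 3, 3), 7.0)
        f = first_order_features(v, np.ones_like(v, bool))
        assert f["Mean"] == 7.0 and f["Variance"] == 0.0
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0

    def test_hand_arithmetic(self):
        v = np.array([1.0, 2, 3, 4]).reshape(4, 1, 1)
        f = first_order_features(v, np.ones_like(v, bool))
        assert f["Mean"] == 2.5
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert f["Energy"] == 30.0
        assert f["Range"] == 3.0

    def test_symmetric_sample_has_zero_skewness(self):
        v = np.array([-2.0, -1, 0, 1, 2]).reshape(5, 1, 1)
        f = first_order_features(v, np.ones_like(v, bool))
        assert abs(f["Skewness"]) < 1e-12

    def test_count_is_eighteen(self):
        v = np.random.default_rng(0).random((3, 3, 3))
        assert len(first_order_features(v, np.ones_like(v, bool))) == 18


class TestNGTDM:
    def test_constant_region_flat(self):
        lv = np.ones((3, 3, 3), dtype=int)
        f = ngtdm_features(lv, np.ones_like(lv, bool))
        assert f["Contrast"] == 0.0 and f["Complexity"] == 0.0

    def test_contrast_matches_bruteforce_3x3(self):
        lv = np.array([[[1], [2], [1]], [[2], [3], [2]], [[1], [2], [1]]])
        mask = np.ones_like(lv, bool)
        f = ngtdm_features(lv, mask)
        assert f["Contrast"] == pytest.approx(ngtdm_bruteforce(lv, mask), abs=1e-9)

    def test_contrast_matches_bruteforce_random(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            lv = rng.integers(1, 5, size=(4, 4, 2))
            mask = rng.random((4, 4, 2)) > 0.2
            if mask.sum() < 3:
                continue
            assert ngtdm_features(lv, mask)["Contrast"] == pytest.approx(
                ngtdm_bruteforce(lv, mask), abs=1e-9)

    def test_checkerboard_contrast_exceeds_blurred(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        vol = (idx % 2).astype(float)
        mask = np.ones_like(vol, bool)
        sharp = discretize(vol, mask, n_bins=4)
        blurred = discretize(binomial_blur(vol, 1), mask, n_bins=4)
        assert ngtdm_features(sharp, mask)["Contrast"] > \
            ngtdm_features(blurred, mask)["Contrast"]

    def test_blur_monotonicity_statistical(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vol = rng.random((7, 7, 7))
            mask = np.ones_like(vol, bool)
            c = [ngtdm_features(discretize(binomial_blur(vol, r) if r else vol,
                                           mask, n_bins=8), mask)["Contrast"]
                 for r in (0, 1, 2)]
            wins += c[0] >= c[1] >= c[2]
        assert wins >= 18


class TestGLCM:
    def test_each_offset_matrix_normalized(self):
        rng = np.random.default_rng(2)
        lv = rng.integers(1, 6, size=(4, 4, 3))
        mask = np.ones_like(lv, bool)
        for off in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
            P = glcm_matrix(lv, mask, off)
            assert P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_constant_region(self):
        lv = np.ones((3, 3, 3), dtype=int)
        f = glcm_features(lv, np.ones_like(lv, bool))
        assert f["Energy"] == pytest.approx(1.0)
        assert f["Contrast"] == 0.0

    def test_contrast_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        lv = rng.integers(1, 4, size=(2, 2, 2))
        mask = np.ones_like(lv, bool)
        for off in [(1, 0, 0), (0, 0, 1), (1, 1, 0)]:
            P = glcm_matrix(lv, mask, off)
            i, j = np.meshgrid(np.arange(1, P.shape[0] + 1),
                               np.arange(1, P.shape[1] + 1), indexing="ij")
            ours = ((i - j) ** 2 * P).sum()
            assert ours == pytest.approx(glcm_contrast_bruteforce(lv, mask, off),
                                         abs=1e-9)

    def test_rotation_invariance_of_averaged_features(self):
        rng = np.random.default_rng(4)
        lv = rng.integers(1, 5, size=(5, 5, 5))
        mask = np.ones_like(lv, bool)
        base = glcm_features(lv, mask)
        rot = glcm_features(np.rot90(lv, axes=(0, 1)), np.rot90(mask, axes=(0, 1)))
        for k in base:
            assert base[k] == pytest.approx(rot[k], abs=1e-9), k


class TestRunZoneDependence:
    def test_glrlm_counts_runs(self):
        # one 1-D line: levels 1 1 2 2 2 1 -> runs (1,2),(2,3),(1,1)
        lv = np.array([1, 1, 2, 2, 2, 1]).reshape(6, 1, 1)
        R = glrlm_matrix(lv, np.ones_like(lv, bool), (1, 0, 0))
        assert R[0, 1] == 1 and R[1, 2] == 1 and R[0, 0] == 1
        assert R.sum() == 3

    def test_glrlm_mask_breaks_runs(self):
        lv = np.array([1, 1, 1, 1]).reshape(4, 1, 1)
        mask = np.array([1, 1, 0, 1], bool).reshape(4, 1, 1)
        R = glrlm_matrix(lv, mask, (1, 0, 0))
        assert R[0, 1] == 1 and R[0, 0] == 1

    def test_glszm_zone_sizes(self):
        lv = np.zeros((4, 4, 1), dtype=int)
        mask = np.ones_like(lv, bool)
        lv[:, :] = 1
        lv[0, 0, 0] = 2
        lv[3, 3, 0] = 2
        Z = glszm_matrix(lv, mask)
        assert Z[1, 0] == 2      # two singleton zones of level 2
        assert Z[0, 13] == 1     # one 14-voxel zone of level 1

    def test_gldm_dependence_of_uniform_volume(self):
        lv = np.ones((3, 3, 3), dtype=int)
        D = gldm_matrix(lv, np.ones_like(lv, bool), alpha=0)
        # centre voxel depends on all 26 neighbours (+ itself -> size 27,
        # stored at column 26); 8 corners have 7 dependent neighbours.
        assert D[0, 26] == 1
        assert D[0, 7] == 8
        assert D.sum() == 27

    def test_rotation_invariance_glrlm(self):
        rng = np.random.default_rng(5)
        from habitatmri.texture import glrlm_features
        lv = rng.integers(1, 4, size=(4, 4, 4))
        mask = np.ones_like(lv, bool)
        a = glrlm_features(lv, mask)
        b = glrlm_features(np.rot90(lv, axes=(1, 2)), np.rot90(mask, axes=(1, 2)))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k


class TestShape:
    def test_single_cube_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (2.0, 2.0, 2.0))
        assert f["VoxelVolume"] == 8.0
        assert f["SurfaceArea"] == 24.0

    def test_sphere_more_spherical_than_slab(self):
        from habitatmri.synth import SynthVolumeSpec, generate_multiphase_study
        ps, _ = generate_multiphase_study(SynthVolumeSpec(seed=0))
        sphere = ps.mask_bool
        slab = np.zeros_like(sphere)
        slab[2:22, 2:22, 11:13] = True
        assert shape_features(sphere)["Sphericity"] > shape_features(slab)["Sphericity"]


class TestExtraction:
    def test_firstorder_only_has_18_names(self):
        rng = np.random.default_rng(6)
        vol = rng.random((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        out = extract_features({"T1_A": vol}, {"tumor": mask},
                               [FeatureSpec(feature_class="firstorder")],
                               include_shape=False)
        assert len(out) == 18
        assert all(k.startswith("T1_A_tumor_original_firstorder_") for k in out)

    def test_empty_region_yields_missing_not_zero(self):
        rng = np.random.default_rng(7)
        vol = rng.random((4, 4, 4))
        out = extract_features({"s": vol}, {"habitat3": np.zeros((4, 4, 4), bool)},
                               [FeatureSpec(feature_class="ngtdm")],
                               include_shape=False)
        assert len(out) == 5 and all(np.isnan(v) for v in out.values())

    def test_extraction_deterministic(self):
        rng = np.random.default_rng(8)
        vol = rng.random((5, 5, 5))
        mask = vol > 0.3
        specs = [FeatureSpec(feature_class=c) for c in ("firstorder", "ngtdm", "glcm")]
        a = extract_features({"s": vol}, {"tumor": mask}, specs)
        b = extract_features({"s": vol}, {"tumor": mask}, specs)
        assert a == b
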