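"""Habitat clustering: CH criterion, k selection, canonical assignment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from habitatmri.habitat import (HabitatClusterer, assign_habitats, build_voxel_space,
                                calinski_harabasz)
from habitatmri.imaging import compute_enhancement_maps
from habitatmri.synth import (SynthVolumeSpec, VoxelMixtureSpec,
                              generate_multiphase_study, generate_voxel_space)


def ch_bruteforce(X, labels):
    """Independent brute-force evaluation of the variance-ratio definition."""
    X = np.asarray(X, float)
    labs = np.unique(labels)
    n, k = len(X), len(labs)
    overall = X.mean(axis=0)
    b = sum(((X[labels == g].mean(axis=0) - overall) ** 2).sum() * (labels == g).sum()
            for g in labs)
    w = sum(((x - X[labels == g].mean(axis=0)) ** 2).sum()
            for g in labs for x in X[labels == g])
    return (b / (k - 1)) / (w / (n - k))


class TestCalinskiHarabasz:
    def test_two_singletons_diverge_to_infinity(self):
        X = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert calinski_harabasz(X, np.array([0, 1])) == np.inf

    def test_matches_bruteforce_on_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(6, 50), 3))
            labels = rng.integers(0, 3, size=len(X))
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz(X, labels) == pytest.approx(
                ch_bruteforce(X, labels), abs=1e-9)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import calinski_harabasz_score
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        labels = rng.integers(0, 4, size=200)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9)

    def test_random_labels_near_permutation_null(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(1000, 3))
        labels = rng.integers(0, 3, size=1000)
        score = calinski_harabasz(X, labels)
        null = [calinski_harabasz(X, rng.permutation(labels)) for _ in range(50)]
        assert abs(score - np.mean(null)) < 3 * np.std(null)

    def test_empty_cluster_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            calinski_harabasz(X, np.array([0, 0, 0, 0]))


class TestKSelection:
    def test_recovers_k3_on_separated_mixture(self, separated_mixture):
        X, true = generate_voxel_space(separated_mixture)
        model = HabitatClusterer(k_candidates=range(2, 10), n_init=4,
                                 random_state=0).fit(X)
        assert model.k_ == 3
        assert adjusted_rand_score(true, model.labels_) >= 0.95

    def test_single_blob_ch_flat_vs_clustered_ch_peaked(self):
        # a single Gaussian blob offers no k a decisive CH advantage over
        # k=2 (scores stay within a narrow band over 20 seeds), while truly
        # clustered data gives the planted k a CH score far above k=2
        rng = np.random.default_rng(3)
        ratios = []
        for rep in range(20):
            X = rng.normal(size=(400, 3))
            m = HabitatClusterer(k_candidates=(2, 3, 4, 5), n_init=2,
                                 random_state=rep).fit(X)
            scores = np.array([m.ch_scores_[k] for k in (2, 3, 4, 5)])
            ratios.append(scores.max() / scores[0])
        assert np.mean(ratios) < 1.3
        X, _ = generate_voxel_space(VoxelMixtureSpec(sigma=0.05, n_voxels=2000,
                                                     seed=0))
        m = HabitatClusterer(k_candidates=(2, 3), n_init=3, random_state=0).fit(X)
        assert m.ch_scores_[3] > 2 * m.ch_scores_[2]

    def test_deterministic_given_seed(self, separated_mixture):
        X, _ = generate_voxel_space(separated_mixture)
        a = HabitatClusterer(k_candidates=(2, 3, 4), n_init=3, random_state=5).fit(X)
        b = HabitatClusterer(k_candidates=(2, 3, 4), n_init=3, random_state=5).fit(X)
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)

    def test_canonical_order_by_arterial_enhancement(self, separated_mixture):
        X, _ = generate_voxel_space(separated_mixture)
        m = HabitatClusterer(k_candidates=(3,), n_init=3, random_state=0).fit(X)
        assert (np.diff(m.cluster_centers_[:, 0]) > 0).all()

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="fewer voxels"):
            HabitatClusterer(k_candidates=(5,)).fit(np.zeros((4, 3)))


class TestAssignment:
    def _fitted(self, n_patients=2, noise_sd=0.0, seed=0):
        maps = {}
        for pid in range(n_patients):
            spec = SynthVolumeSpec(grid_shape=(14, 14, 14), tumor_radius=5.0,
                                   noise_sd=noise_sd,
                                   mixture=VoxelMixtureSpec(sigma=0.02,
                                                            n_voxels=1,
                                                            seed=seed + pid),
                                   seed=seed + pid)
            ps, hab = generate_multiphase_study(spec)
            maps[pid] = (compute_enhancement_maps(ps, mode="ratio", epsilon=0.0), hab)
        em = {pid: m for pid, (m, _) in maps.items()}
        truth = {pid: h for pid, (_, h) in maps.items()}
        space = build_voxel_space(em, subsample_cap=None)
        model = HabitatClusterer(k_candidates=(3,), n_init=4, random_state=0).fit(space.X)
        return model, em, truth, space

    def test_noiseless_recovery_is_exact(self):
        model, em, truth, space = self._fitted(noise_sd=0.0)
        labeling = assign_habitats(model, em, space.transform)
        for pid, vol in labeling.label_volumes.items():
            m = em[pid].mask.data > 0.5
            assert adjusted_rand_score(truth[pid][m], vol[m]) == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        model, em, truth, space = self._fitted(noise_sd=1.0)
        labeling = assign_habitats(model, em, space.transform)
        sums = labeling.proportions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert labeling.cohort_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_voxel_at_centroid_gets_its_label(self, separated_mixture):
        X, _ = generate_voxel_space(separated_mixture)
        m = HabitatClusterer(k_candidates=(3,), n_init=3, random_state=0).fit(X)
        assert (m.predict(m.cluster_centers_) == np.arange(3)).all()

    def test_unfitted_model_rejected(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            HabitatClusterer().predict(np.zeros((2, 3)))


class TestVoxelSpace:
    def test_row_bookkeeping_across_patients(self):
        spec1 = SynthVolumeSpec(grid_shape=(10, 10, 10), tumor_radius=2.0, seed=0)
        spec2 = SynthVolumeSpec(grid_shape=(10, 10, 10), tumor_radius=3.0, seed=1)
        em = {}
        masks = {}
        for pid, spec in enumerate((spec1, spec2)):
            ps, _ = generate_multiphase_study(spec)
            em[pid] = compute_enhancement_maps(ps)
            masks[pid] = int(ps.mask.data.sum())
        space = build_voxel_space(em, subsample_cap=None)
        assert len(space.X) == masks[0] + masks[1]
        assert (space.patient_ids == 0).sum() == masks[0]

    def test_subsample_cap_reproducible(self):
        spec = SynthVolumeSpec(seed=2)
        ps, _ = generate_multiphase_study(spec)
        em = {0: compute_enhancement_maps(ps)}
        a = build_voxel_space(em, subsample_cap=500, seed=9)
        b = build_voxel_space(em, subsample_cap=500, seed=9)
        assert len(a.X) == 500
        np.testing.assert_array_equal(a.X, b.X)

    def test_recovered_proportion_of_largest_habitat(self, separated_mixture):
        X, _ = generate_voxel_space(separated_mixture)
        m = HabitatClusterer(k_candidates=range(2, 10), n_init=4, random_state=1).fit(X)
        prop = np.bincount(m.predict(X)).max() / len(X)
        assert abs(prop - 0.464) <= 0.02
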