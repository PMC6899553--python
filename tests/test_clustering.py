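import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mpasl import (MultiPhaseSeries, cluster_average_series,
                   cluster_mean_phases, circular_mean_deg,
                   phase_consistency, phase_supervoxel_clustering)


def quadrant_truth(shape=(32, 32, 10)):
    nx, ny, nz = shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    quad = (xx >= nx // 2) * 2 + (yy >= ny // 2)
    return np.repeat(quad[:, :, None], nz, axis=2) + 1


class TestPhaseSupervoxelClustering:
    def test_uniform_phase_map(self):
        phase = np.full((16, 16, 6), 42.0)
        mask = np.ones(phase.shape, bool)
        labels = phase_supervoxel_clustering(phase, mask, seed=0)
        means = cluster_mean_phases(phase, labels)
        for m in means.values():
            assert m == pytest.approx(42.0, abs=1e-6)

    def test_two_territories_recovered(self):
        rng = np.random.default_rng(0)
        truth = (quadrant_truth((24, 24, 8)) > 2).astype(int)  # halves
        phase = np.where(truth == 1, 40.0, 0.0) + rng.normal(0, 5.0, truth.shape)
        mask = np.ones(truth.shape, bool)
        labels = phase_supervoxel_clustering(phase % 360.0, mask,
                                             n_classes=2, seed=1)
        ari = adjusted_rand_score(truth.ravel(), labels.ravel())
        assert ari > 0.95

    def test_four_quadrants_phase_recovery(self):
        rng = np.random.default_rng(3)
        truth = quadrant_truth((28, 28, 8))
        phis = np.array([0.0, 15.0, 30.0, 45.0])
        phase = (phis[truth - 1] + rng.normal(0, 5.0, truth.shape)) % 360.0
        mask = np.ones(truth.shape, bool)
        labels = phase_supervoxel_clustering(phase, mask, n_classes=4, seed=0)
        means = cluster_mean_phases(phase, labels)
        got = np.sort([v if v < 180 else v - 360 for v in means.values()])
        assert np.allclose(got, phis, atol=3.0)

    def test_shift_invariance_of_partition(self):
        rng = np.random.default_rng(5)
        truth = quadrant_truth((20, 20, 6))
        phis = np.array([0.0, 20.0, 40.0, 60.0])
        noise = rng.normal(0, 4.0, truth.shape)
        mask = np.ones(truth.shape, bool)
        a = phase_supervoxel_clustering((phis[truth - 1] + noise) % 360.0,
                                        mask, seed=2)
        b = phase_supervoxel_clustering((phis[truth - 1] + noise + 200.0) % 360.0,
                                        mask, seed=2)
        assert adjusted_rand_score(a.ravel(), b.ravel()) > 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        phase = rng.uniform(0, 360, (12, 12, 4))
        mask = np.ones(phase.shape, bool)
        a = phase_supervoxel_clustering(phase, mask, seed=7)
        b = phase_supervoxel_clustering(phase, mask, seed=7)
        assert np.array_equal(a, b)

    def test_errors(self):
        phase = np.zeros((8, 8, 4))
        with pytest.raises(ValueError):
            phase_supervoxel_clustering(phase, np.zeros(phase.shape, bool))
        tiny = np.zeros(phase.shape, bool)
        tiny[0, 0, 0] = True
        with pytest.raises(ValueError):
            phase_supervoxel_clustering(phase, tiny, n_classes=4)


class TestClusterAverageSeries:
    thetas = np.arange(8) * 45.0

    def test_single_voxel_cluster(self):
        data = np.zeros((2, 1, 1, 8))
        data[0, 0, 0] = np.arange(8.0)
        data[1, 0, 0] = 7.0
        cmap = np.array([[[1]], [[2]]])
        out = cluster_average_series(data, cmap, self.thetas)
        assert np.allclose(out[1].mean_values, np.arange(8.0))
        assert out[1].weight == 1

    def test_identical_signals_average_unchanged(self):
        sig = np.sin(np.deg2rad(self.thetas)) + 5.0
        data = np.tile(sig, (4, 4, 2, 1))
        cmap = np.ones((4, 4, 2), int)
        out = cluster_average_series(data, cmap, self.thetas)
        assert np.allclose(out[1].mean_values, sig)
        assert out[1].weight == 32

    def test_noise_reduction_scaling(self):
        rng = np.random.default_rng(1)
        sigma, M = 3.0, 400
        data = rng.normal(0.0, sigma, (M, 1, 1, 8))
        cmap = np.ones((M, 1, 1), int)
        out = cluster_average_series(data, cmap, self.thetas)
        sd = out[1].mean_values.std()
        assert sd == pytest.approx(sigma / np.sqrt(M), rel=0.6)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            cluster_average_series(np.zeros((2, 2, 2, 8)), np.ones((3, 3, 3), int),
                                   self.thetas)


class TestPhaseConsistency:
    @pytest.mark.parametrize("phis,expected", [
        ([10.0, 10.0, 10.0, 10.0], 0.0),
        ([0.0, 10.0, 20.0, 30.0], (10 + 20 + 30 + 10 + 20 + 10) / 6.0),
        ([350.0, 10.0, 10.0, 10.0], (20 + 20 + 20 + 0 + 0 + 0) / 6.0),
    ])
    def test_examples(self, phis, expected):
        assert phase_consistency(phis) == pytest.approx(expected)

    def test_too_few(self):
        with pytest.raises(ValueError):
            phase_consistency([10.0])


class TestCircularMean:
    def test_wraparound(self):
        assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)

    def test_plain(self):
        assert circular_mean_deg([10.0, 20.0]) == pytest.approx(15.0)
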