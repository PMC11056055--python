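"""The synthetic data-generating process and its invariants."""

import numpy as np
import pytest

from stcar.simulate import (
    Scenario,
    _zero_truncated_poisson,
    build_knn_adjacency,
    compute_vif,
    equicorrelation_matrix,
    generate_covariates,
    generate_noise,
    generate_panel,
    train_test_split,
)


class TestEquicorrelation:
    def test_structure(self):
        m = equicorrelation_matrix(3, 0.05)
        assert np.allclose(m, [[1, 0.05, 0.05], [0.05, 1, 0.05], [0.05, 0.05, 1]])

    def test_zero_is_identity(self):
        assert np.array_equal(equicorrelation_matrix(5, 0.0), np.eye(5))

    def test_closed_form_eigenvalues(self):
        eigs = np.linalg.eigvalsh(equicorrelation_matrix(54, 0.95))
        assert eigs.min() == pytest.approx(0.05)
        assert eigs.max() == pytest.approx(1 + 53 * 0.95)

    @pytest.mark.parametrize("r", [-0.1, 1.0, 1.5])
    def test_invalid_r(self, r):
        with pytest.raises(ValueError):
            equicorrelation_matrix(3, r)


class TestGenerateNoise:
    def test_seeded_reproducibility(self):
        sc = Scenario(sp=0.3, tm=0.7, n_units=8, n_times=5)
        s1, t1 = generate_noise(sc, np.random.default_rng(11))
        s2, t2 = generate_noise(sc, np.random.default_rng(11))
        assert np.array_equal(s1, s2) and np.array_equal(t1, t2)

    @pytest.mark.parametrize("target", [0.05, 0.95])
    def test_sample_correlation_matches_target(self, target):
        """Monte-Carlo check: the empirical covariance of the noise converges
        to the specified equicorrelation matrix."""
        dim = 8
        sc = Scenario(sp=target, tm=target, n_units=dim, n_times=dim)
        rng = np.random.default_rng(5)
        draws = np.array([generate_noise(sc, rng)[0] for _ in range(20_000)])
        emp = np.cov(draws, rowvar=False)
        assert np.abs(emp - equicorrelation_matrix(dim, target)).max() < 0.05


class TestCovariates:
    def test_vif_exactly_one(self):
        X = generate_covariates(54, 20, p=10, rng=np.random.default_rng(0))
        assert np.allclose(compute_vif(X), 1.0, atol=1e-6)

    def test_standardization(self):
        X = generate_covariates(20, 10, p=6, rng=np.random.default_rng(1))
        flat = X.reshape(-1, 6)
        assert np.abs(flat.mean(axis=0)).max() < 1e-10
        assert np.abs(flat.std(axis=0) - 1).max() < 1e-10

    def test_single_column(self):
        X = generate_covariates(10, 4, p=1, rng=np.random.default_rng(2))
        assert compute_vif(X)[0] == pytest.approx(1.0)

    def test_too_many_columns(self):
        with pytest.raises(ValueError):
            generate_covariates(3, 2, p=6)


class TestVif:
    def test_known_pairwise_correlation(self):
        """For two columns with correlation r, VIF = 1 / (1 - r^2)."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=200_000)
        e = rng.normal(size=200_000)
        r = 0.8
        x2 = r * z + np.sqrt(1 - r * r) * e
        vif = compute_vif(np.column_stack([z, x2]))
        assert np.allclose(vif, 1.0 / (1.0 - 0.64), atol=0.05)

    def test_duplicated_column_is_infinite(self):
        x = np.random.default_rng(4).normal(size=50)
        vif = compute_vif(np.column_stack([x, x, np.random.default_rng(5).normal(size=50)]))
        assert np.isinf(vif[0]) and np.isinf(vif[1])
        assert np.isfinite(vif[2])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            compute_vif(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestKnnAdjacency:
    def test_collinear_points(self):
        g = build_knn_adjacency(np.array([[0.0, 0], [1, 0], [2, 0]]), k=1)
        assert g.W[1, 0] == 1 and g.W[1, 2] == 1

    def test_contract(self, rng):
        g = build_knn_adjacency(rng.normal(size=(15, 2)), k=4)
        assert np.array_equal(g.W, g.W.T)
        assert np.all(np.diag(g.W) == 0)
        assert g.degrees.min() >= 4  # each unit keeps at least its own k links

    def test_complete_graph(self, rng):
        g = build_knn_adjacency(rng.normal(size=(5, 2)), k=4)
        assert g.W.sum() == 5 * 4

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            build_knn_adjacency(rng.normal(size=(5, 2)), k=5)


class TestZeroTruncatedPoisson:
    def test_mean_at_unit_intensity(self):
        """E[y] for zero-truncated Poisson(1) is 1/(1 - e^-1) ~ 1.582."""
        rng = np.random.default_rng(6)
        y = _zero_truncated_poisson(np.ones(200_000), rng)
        assert y.min() >= 1
        assert y.mean() == pytest.approx(1.0 / (1.0 - np.exp(-1.0)), abs=0.01)

    def test_small_intensity_branch(self):
        rng = np.random.default_rng(7)
        y = _zero_truncated_poisson(np.full(50_000, 0.01), rng)
        assert y.min() >= 1
        # P(y >= 2 | y >= 1) = (1 - e^-l - l e^-l) / (1 - e^-l) ~ l/2 for small l
        assert (y >= 2).mean() == pytest.approx(0.005, abs=0.002)


class TestGeneratePanel:
    def test_study_dimensions_give_1080_records(self):
        panel = generate_panel(Scenario(sp=0.25, tm=0.25, seed=1))
        assert panel.n_records == 54 * 20
        assert panel.y.min() >= 1

    def test_bit_reproducible(self):
        sc = Scenario(sp=0.15, tm=0.85, n_units=10, n_times=5, seed=9)
        p1, p2 = generate_panel(sc), generate_panel(sc)
        assert np.array_equal(p1.y, p2.y)
        assert np.array_equal(p1.X, p2.X)
        assert np.array_equal(p1.graph.W, p2.graph.W)

    def test_latent_decomposition(self):
        """The spatial term is constant over time and the temporal term
        constant across units, so log lambda has exact rank-1 structure."""
        panel = generate_panel(Scenario(sp=0.5, tm=0.5, n_units=9, n_times=7, seed=3))
        g = np.log(panel.lam)
        recon = g.mean(axis=1, keepdims=True) + g.mean(axis=0, keepdims=True) - g.mean()
        assert np.allclose(g, recon, atol=1e-10)

    def test_latent_bound_rescales(self, caplog):
        sc = Scenario(sp=0.5, tm=0.5, n_units=30, n_times=10, seed=2)
        panel = generate_panel(sc, latent_bound=0.5)
        assert np.abs(np.log(panel.lam)).max() <= 0.5 + 1e-12

    def test_fresh_spatial_noise_option(self):
        sc = Scenario(sp=0.5, tm=0.5, n_units=8, n_times=6, seed=4)
        panel = generate_panel(sc, fresh_spatial_noise_per_time=True)
        g = np.log(panel.lam)
        col_dev = g - g.mean(axis=0, keepdims=True)
        assert np.ptp(col_dev, axis=1).max() > 1e-8  # spatial part varies over time

    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            Scenario(sp=0.0, tm=0.5)


class TestTrainTestSplit:
    def test_seventy_thirty_on_study_size(self):
        panel = generate_panel(Scenario(sp=0.25, tm=0.25, seed=1))
        split = train_test_split(panel, 0.7, np.random.default_rng(0))
        assert split.train_index.size == 756
        assert split.test_index.size == 324

    def test_reproducible_partition(self):
        panel = generate_panel(Scenario(sp=0.25, tm=0.25, n_units=6, n_times=5, seed=1))
        s1 = train_test_split(panel, 0.7, np.random.default_rng(3))
        s2 = train_test_split(panel, 0.7, np.random.default_rng(3))
        assert np.array_equal(s1.train_index, s2.train_index)

    def test_half_split(self):
        panel = generate_panel(
            Scenario(sp=0.25, tm=0.25, n_units=5, n_times=4, seed=1), p=3
        )
        split = train_test_split(panel, 0.5, np.random.default_rng(1))
        assert split.train_index.size == 10 and split.test_index.size == 10
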