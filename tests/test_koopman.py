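"""Koopman estimation, VAMP-2 scoring, one-step prediction, subspace reduction."""

import numpy as np
import pytest

from torsiondyn import (
    GeneratorConfig,
    KoopmanRegressor,
    displacement,
    embed_sincos,
    estimate_koopman,
    generate_linear_observable_process,
    generate_torsional_trajectory,
    lagged_covariances,
    optimal_scale,
    predict_one_step,
    reduce_to_subspace,
    vamp2_score,
)


def stable_matrix(d, seed, scale=0.95):
    """Well-conditioned contraction: random orthogonal matrix times scale."""
    Q = np.linalg.qr(np.random.default_rng(seed).standard_normal((d, d)))[0]
    return scale * Q


class TestLaggedCovariances:
    def test_iid_noise_limits(self, rng):
        Z = rng.standard_normal((20000, 4))
        cov = lagged_covariances(Z, lag=1)
        tol = 3.0 / np.sqrt(Z.shape[0])
        np.testing.assert_allclose(cov.C00, np.eye(4), atol=tol)
        np.testing.assert_allclose(cov.C01, 0.0, atol=tol)
        assert cov.sample_count == 19999

    def test_constant_series_is_zero(self):
        cov = lagged_covariances(np.ones((50, 3)), lag=2)
        np.testing.assert_array_equal(cov.C00, 0.0)
        np.testing.assert_array_equal(cov.C01, 0.0)

    def test_time_reversal_transposes_cross_covariance(self, rng):
        Z = rng.standard_normal((500, 3))
        fwd = lagged_covariances(Z, lag=1)
        # direct-sum oracle on the same pairs, reversed roles
        A = Z[:-1] - Z[:-1].mean(axis=0)
        B = Z[1:] - Z[1:].mean(axis=0)
        np.testing.assert_allclose(fwd.C01, (A.T @ B) / A.shape[0], atol=1e-12)
        rev = lagged_covariances(Z[::-1], lag=1)
        np.testing.assert_allclose(rev.C01, fwd.C01.T, atol=1e-12)

    def test_lag_validation(self):
        with pytest.raises(ValueError):
            lagged_covariances(np.zeros((5, 2)), lag=5)


class TestEstimateKoopman:
    def test_planted_linear_system_recovery(self):
        A = stable_matrix(6, seed=2)
        Z = generate_linear_observable_process(A, noise=0.0, n_frames=500, seed=3)
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        np.testing.assert_allclose(model.K, A, atol=1e-8)

    def test_random_walk_gives_identity(self, rng):
        # identity dynamics excited by noise: K approaches the identity
        Z = np.cumsum(rng.standard_normal((20000, 3)), axis=0)
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        np.testing.assert_allclose(model.K, np.eye(3), atol=0.05)

    def test_matches_least_squares_regression_oracle(self, rng):
        Z = generate_linear_observable_process(
            stable_matrix(4, seed=9), noise=0.5, n_frames=800, seed=10
        )
        model = estimate_koopman(lagged_covariances(Z, lag=2))
        A = Z[:-2] - Z[:-2].mean(axis=0)
        B = Z[2:] - Z[2:].mean(axis=0)
        K_lstsq, *_ = np.linalg.lstsq(A, B, rcond=None)
        np.testing.assert_allclose(model.K, K_lstsq, atol=1e-8)

    def test_zero_variance_feature_flagged(self, rng):
        Z = rng.standard_normal((300, 3))
        Z[:, 1] = 5.0  # constant feature
        with pytest.warns(UserWarning, match="rank deficient"):
            model = estimate_koopman(lagged_covariances(Z, lag=1))
        assert model.rank == 2

    def test_singular_values_bounded_for_well_sampled_data(self, rng):
        Z = generate_linear_observable_process(
            stable_matrix(3, seed=4, scale=0.8), noise=1.0, n_frames=5000, seed=5
        )
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        assert np.all(model.singular_values <= 1.0 + 1e-6)
        assert np.all(np.diff(model.singular_values) <= 1e-12)


class TestVamp2Score:
    def test_iid_noise_scores_one(self):
        Z = np.random.default_rng(42).standard_normal((20000, 6))
        assert vamp2_score(Z, lag=1) == pytest.approx(1.0, abs=0.1)

    def test_lag_periodic_identity_dynamics_scores_one_plus_d(self, rng):
        # zeta_{t+6} = zeta_t exactly with full-rank excitation: all four
        # nonconstant features are perfectly predictable, score = 1 + d
        block = rng.standard_normal((6, 4))
        Z = np.tile(block, (60, 1))
        assert vamp2_score(Z, lag=6) == pytest.approx(5.0, abs=1e-6)

    def test_invariant_under_affine_refeaturization(self, rng):
        Z = generate_linear_observable_process(
            stable_matrix(4, seed=6), noise=0.5, n_frames=2000, seed=7
        )
        M = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        s1 = vamp2_score(Z, lag=1)
        s2 = vamp2_score(Z @ M + rng.standard_normal(4), lag=1)
        assert s1 == pytest.approx(s2, rel=1e-6)

    def test_two_timescale_representation_ordering(self):
        traj = generate_torsional_trajectory(GeneratorConfig(n_frames=6000, seed=7))
        theta = traj.values
        sincos = embed_sincos(traj).values
        chi = displacement(traj).values
        for lag in range(1, 11):
            s_sc = vamp2_score(sincos, lag=lag)
            s_th = vamp2_score(theta, lag=lag)
            s_chi = vamp2_score(chi, lag=lag)
            assert s_sc >= s_th >= s_chi

    def test_singular_values_decay_with_lag(self):
        traj = generate_torsional_trajectory(
            GeneratorConfig(n_frames=6000, seed=13, jump_rate=0.0)
        )
        sincos = embed_sincos(traj).values
        tops = [
            estimate_koopman(lagged_covariances(sincos, lag)).singular_values[:3].sum()
            for lag in (1, 5, 10)
        ]
        assert tops[0] >= tops[1] - 0.02 >= tops[2] - 0.04


class TestPrediction:
    def test_planted_system_prediction(self):
        A = stable_matrix(5, seed=8)
        Z = generate_linear_observable_process(A, noise=0.0, n_frames=400, seed=9)
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        pred = predict_one_step(model, Z[:-1])
        np.testing.assert_allclose(pred, Z[1:], atol=1e-6)

    def test_mean_maps_to_lagged_mean(self, rng):
        Z = generate_linear_observable_process(
            stable_matrix(3, seed=10), noise=0.3, n_frames=600, seed=11
        )
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        np.testing.assert_allclose(
            predict_one_step(model, model.covariances.mu0),
            model.covariances.mut,
            atol=1e-10,
        )

    def test_no_worse_than_persistence_on_linear_system(self):
        A = stable_matrix(4, seed=12, scale=0.9)
        Z = generate_linear_observable_process(A, noise=0.4, n_frames=2000, seed=13)
        train, val = Z[:1500], Z[1500:]
        model = estimate_koopman(lagged_covariances(train, lag=1))
        pred = predict_one_step(model, val[:100])
        err_koopman = np.linalg.norm(pred - val[1:101], axis=1).mean()
        err_persist = np.linalg.norm(val[:100] - val[1:101], axis=1).mean()
        assert err_koopman <= err_persist

    def test_sklearn_estimator_interface(self):
        A = stable_matrix(3, seed=14)
        Z = generate_linear_observable_process(A, noise=0.1, n_frames=500, seed=15)
        reg = KoopmanRegressor(lag=1).fit(Z)
        assert reg.get_params() == {"lag": 1, "floor_scale": 1e-10}
        assert reg.predict(Z[:10]).shape == (10, 3)
        assert reg.score(Z) > 1.0


class TestOptimalScale:
    def test_trivial_cases(self, rng):
        X = rng.standard_normal((5, 3))
        assert optimal_scale(X, X) == pytest.approx(1.0)
        assert optimal_scale(X / 2, X) == pytest.approx(2.0)

    def test_norm_matching_property(self, rng):
        P = rng.standard_normal((7, 2))
        R = rng.standard_normal((7, 2))
        alpha = optimal_scale(P, R)
        assert np.linalg.norm(alpha * P) == pytest.approx(np.linalg.norm(R))

    def test_zero_prediction_rejected(self):
        with pytest.raises(ValueError):
            optimal_scale(np.zeros((2, 2)), np.ones((2, 2)))


class TestReduceToSubspace:
    def test_identity_projection(self, rng):
        K = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(reduce_to_subspace(K, np.eye(4)), K)

    def test_full_rank_orthogonal_preserves_spectrum(self, rng):
        K = rng.standard_normal((5, 5))
        Q = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvals(reduce_to_subspace(K, Q)).real),
            np.sort(np.linalg.eigvals(K).real),
            atol=1e-8,
        )

    def test_confined_dynamics_consistency(self, rng):
        # dynamics confined to span(V): reduce-then-predict == project-prediction
        V = np.linalg.qr(rng.standard_normal((6, 2)))[0]
        A_red = stable_matrix(2, seed=16, scale=0.9)
        Y = generate_linear_observable_process(A_red, noise=0.2, n_frames=2000, seed=17)
        Z = Y @ V.T
        model = estimate_koopman(lagged_covariances(Z, lag=1))
        K_y = reduce_to_subspace(model.K, V)
        z = Z[100]
        full = (z - 0) @ model.K  # mean-free by construction up to sampling
        np.testing.assert_allclose((z @ V) @ K_y @ V.T, full @ V @ V.T, atol=1e-8)
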