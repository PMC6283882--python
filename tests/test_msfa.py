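import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from aabnet.msfa import (
    MSFAParams,
    apply_identifiability,
    choose_dimensions,
    ecm_fit,
    loadings_frame,
    log_likelihood,
    marginal_covariance,
    n_free_parameters,
)
from aabnet.simulate import generate_params


def simulate_from(params: MSFAParams, n_per_study, rng):
    data = []
    for s in range(params.n_studies):
        n = n_per_study if np.isscalar(n_per_study) else n_per_study[s]
        f = rng.standard_normal((n, params.K))
        l = rng.standard_normal((n, params.Phi[s].shape[1]))
        e = rng.standard_normal((n, params.p)) * np.sqrt(params.Psi[s])
        data.append(params.mu[s] + f @ params.Lambda.T + l @ params.Phi[s].T + e)
    return data


class TestMarginalCovariance:
    def test_no_factors_diagonal(self):
        params = MSFAParams(
            Lambda=np.zeros((4, 0)), Phi=[np.zeros((4, 0))],
            Psi=[np.array([1.0, 2.0, 3.0, 4.0])], mu=[np.zeros(4)],
        )
        np.testing.assert_allclose(
            marginal_covariance(params, 0), np.diag([1.0, 2.0, 3.0, 4.0])
        )

    def test_unit_vector_loading_analytic(self):
        Lam = np.zeros((3, 1))
        Lam[0, 0] = 1.0
        params = MSFAParams(Lambda=Lam, Phi=[np.zeros((3, 0))],
                            Psi=[np.ones(3)], mu=[np.zeros(3)])
        sigma = marginal_covariance(params, 0)
        expected = np.eye(3)
        expected[0, 0] = 2.0
        np.testing.assert_allclose(sigma, expected)

    def test_matches_triple_product_oracle(self, rng):
        params = generate_params(5, 2, 1, 2, seed=2)
        for s in range(2):
            oracle = (
                params.Lambda @ params.Lambda.T
                + params.Phi[s] @ params.Phi[s].T
                + np.diag(params.Psi[s])
            )
            np.testing.assert_allclose(marginal_covariance(params, s), oracle, atol=1e-12)

    def test_positive_definite(self, rng):
        params = generate_params(8, 3, 2, 3, seed=5)
        for s in range(3):
            w = np.linalg.eigvalsh(marginal_covariance(params, s))
            assert w.min() > 0


class TestLogLikelihood:
    def test_single_point_at_mean_identity_covariance(self):
        p = 4
        params = MSFAParams(Lambda=np.zeros((p, 0)), Phi=[np.zeros((p, 0))],
                            Psi=[np.ones(p)], mu=[np.full(p, 2.0)])
        ll = log_likelihood([np.full((1, p), 2.0)], params)
        assert ll == pytest.approx(-(p / 2) * np.log(2 * np.pi), abs=1e-12)

    def test_matches_direct_density_oracle(self, rng):
        params = generate_params(4, 1, 1, 2, seed=3)
        data = simulate_from(params, 6, rng)
        ll = log_likelihood(data, params)
        oracle = 0.0
        for s, X in enumerate(data):
            sigma = marginal_covariance(params, s)
            oracle += stats.multivariate_normal(params.mu[s], sigma).logpdf(X).sum()
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_rotation_invariance(self, rng):
        params = generate_params(6, 2, 0, 1, seed=4)
        data = simulate_from(params, 20, rng)
        Q = linalg.qr(rng.normal(size=(2, 2)))[0]
        rotated = params.copy()
        rotated.Lambda = params.Lambda @ Q
        assert log_likelihood(data, rotated) == pytest.approx(
            log_likelihood(data, params), abs=1e-9
        )


class TestEcmFit:
    def test_infinite_tol_returns_initialization(self, rng):
        params = generate_params(6, 1, 0, 2, seed=6)
        data = simulate_from(params, 40, rng)
        fit = ecm_fit(data, K=1, J=0, tol=np.inf)
        assert fit.n_iter == 0
        assert len(fit.loglik_trace) == 1

    def test_monotone_loglik_small_battery(self, rng):
        for seed in range(5):
            params = generate_params(8, 2, 1, 2, seed=seed)
            data = simulate_from(params, 60, rng)
            fit = ecm_fit(data, K=2, J=1, max_iter=150)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_dimension_guard(self, rng):
        params = generate_params(5, 1, 0, 1, seed=1)
        data = simulate_from(params, 30, rng)
        with pytest.raises(ValueError, match="must be <"):
            ecm_fit(data, K=4, J=1)

    def test_mismatched_analyte_sets(self, rng):
        with pytest.raises(ValueError, match="share the analyte set"):
            ecm_fit([rng.normal(size=(20, 4)), rng.normal(size=(20, 5))], K=1, J=0)

    def test_identifiability_constraint_applied(self, rng):
        params = generate_params(8, 3, 1, 2, seed=8)
        data = simulate_from(params, 200, rng)
        fit = ecm_fit(data, K=3, J=1, max_iter=200)
        top = fit.params.Lambda[:3, :]
        np.testing.assert_allclose(top, np.tril(top), atol=1e-10)
        assert np.all(np.diag(top) >= 0)

    def test_identifiability_preserves_products(self, rng):
        params = generate_params(6, 2, 1, 2, seed=9)
        rotated = apply_identifiability(params)
        np.testing.assert_allclose(
            rotated.Lambda @ rotated.Lambda.T,
            params.Lambda @ params.Lambda.T,
            atol=1e-10,
        )

    def test_common_structure_recovery(self, rng):
        # truth has only common factors; the common block should capture them
        truth = generate_params(12, 2, 0, 3, sparsity=0.2, seed=10)
        data = simulate_from(truth, 500, rng)
        fit = ecm_fit(data, K=2, J=1, max_iter=500)
        pooled_sd = np.vstack(data).std(axis=0, ddof=1)
        Lt = truth.Lambda / pooled_sd[:, None]
        LLt = Lt @ Lt.T
        LLf = fit.params.Lambda @ fit.params.Lambda.T
        rel = np.linalg.norm(LLf - LLt) / np.linalg.norm(LLt)
        assert rel < 0.2

    def test_random_init_multistart_seeded(self, rng):
        params = generate_params(6, 1, 0, 2, seed=12)
        data = simulate_from(params, 80, rng)
        a = ecm_fit(data, K=1, J=0, init="random", n_starts=3, seed=7, max_iter=100)
        b = ecm_fit(data, K=1, J=0, init="random", n_starts=3, seed=7, max_iter=100)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-10)
        np.testing.assert_allclose(a.params.Lambda, b.params.Lambda, atol=1e-10)


class TestChooseDimensions:
    def test_single_grid_point_trivial(self, rng):
        params = generate_params(6, 1, 0, 2, seed=13)
        data = simulate_from(params, 100, rng)
        K, J, table = choose_dimensions(data, [1], [0], max_iter=100)
        assert (K, J) == (1, 0)
        assert len(table) == 1

    def test_bic_prefers_true_dimension(self, rng):
        hits = 0
        for seed in range(5):
            truth = generate_params(10, 2, 0, 2, sparsity=0.0, seed=seed + 40)
            data = simulate_from(truth, 400, rng)
            K, _, _ = choose_dimensions(data, [1, 2, 3], [0], max_iter=200)
            hits += K == 2
        assert hits >= 4

    def test_pure_noise_selects_smallest(self, rng):
        data = [rng.standard_normal((300, 8)) for _ in range(2)]
        K, J, _ = choose_dimensions(data, [1, 2, 3], [0], max_iter=200)
        assert K == 1

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_dimensions([rng.normal(size=(10, 4))], [], [0])


class TestExports:
    def test_parameter_count_formula(self):
        # p=10, K=2, J=[1,1]: common 20-1, specific 2*10, Psi 2*10, mu 2*10
        assert n_free_parameters(10, 2, [1, 1]) == 19 + 20 + 20 + 20

    def test_loadings_frame_roundtrip(self, rng, tmp_path):
        params = generate_params(6, 2, 1, 2, seed=15)
        data = simulate_from(params, 120, rng)
        fit = ecm_fit(data, K=2, J=1, max_iter=100)
        frame = loadings_frame(fit, ["HD", "SSc"])
        path = tmp_path / "loadings.csv"
        frame.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(
            back[["common_1", "common_2"]].to_numpy(), fit.params.Lambda, atol=1e-12
        )
        assert "HD_specific_1" in back.columns
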