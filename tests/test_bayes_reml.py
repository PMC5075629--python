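"""ReML core tests: components, free energy, ascent, recovery, inverse."""

import numpy as np
import pytest
from scipy import stats

from stfmri_esi.bayes_reml import (
    HyperPrior,
    NoiseModel,
    assemble_R,
    free_energy,
    inverse_solution,
    reml_estimate,
    sensor_covariance_components,
)
from stfmri_esi.fmri_priors import build_components


def _rand_psd(m, rng, rank=None):
    A = rng.standard_normal((m, rank or m))
    return A @ A.T / m


class TestSensorComponents:
    def test_no_priors_gives_noise_only(self):
        from stfmri_esi.fmri_priors import PriorSet

        G = np.ones((4, 6))
        pr = PriorSet(submaps=[], components=[], source_count=6)
        K = sensor_covariance_components(G, pr, NoiseModel(C=np.eye(4)))
        assert len(K) == 1 and np.array_equal(K[0], np.eye(4))

    def test_singleton_indicator_is_column_outer_product(self):
        rng = np.random.default_rng(1)
        G = rng.standard_normal((5, 8))
        pr = build_components([np.array([3])], 8)
        K = sensor_covariance_components(G, pr, NoiseModel(C=np.eye(5)))
        assert np.allclose(K[1], np.outer(G[:, 3], G[:, 3]), atol=1e-15)

    @pytest.mark.parametrize("encoding", ["indicator-rank1", "diagonal"])
    def test_matches_dense_triple_product(self, encoding):
        rng = np.random.default_rng(7)
        G = rng.standard_normal((6, 12))
        subs = [np.array([0, 2, 5]), np.array([7, 8])]
        pr = build_components(subs, 12, encoding=encoding)
        K = sensor_covariance_components(G, pr, NoiseModel(C=np.eye(6)))
        for comp, Ki in zip(pr.components, K[1:]):
            dense = G @ comp.dense(12) @ G.T
            assert np.abs(Ki - dense).max() < 1e-12 * max(np.abs(dense).max(), 1.0)

    def test_dimension_mismatch_reported(self):
        from stfmri_esi.fmri_priors import PriorSet
        pr = PriorSet(submaps=[], components=[], source_count=9)
        with pytest.raises(ValueError, match="9"):
            sensor_covariance_components(np.ones((4, 6)), pr, NoiseModel(C=np.eye(4)))


class TestFreeEnergy:
    def test_standard_normal_data_terms(self):
        """m=1, d=1, Σ=1, Y=0: the data terms are the standard normal
        log-density at zero, −½ln2π."""
        hyper = HyperPrior()
        K = [np.array([[np.exp(-hyper.eta)]])]  # Σ = e^η·e^{−η} = 1 at λ=η
        F, parts = free_energy(np.zeros((1, 1)), K, [hyper.eta], hyper,
                               return_parts=True)
        assert parts["data"] == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)
        assert parts["prior"] == 0.0

    def test_prior_penalty_quadratic(self):
        """Moving λ by δ off the prior mean costs exactly ½Πδ² in the prior
        term, holding the data fixed."""
        hyper = HyperPrior(eta=-2.0, pi=4.0)
        Y = np.random.default_rng(0).standard_normal((1, 10))
        K = [np.eye(1)]
        delta = 0.7
        _, at_eta = free_energy(Y, K, [hyper.eta], hyper, return_parts=True)
        _, off = free_energy(Y, K, [hyper.eta + delta], hyper, return_parts=True)
        assert at_eta["prior"] == 0.0
        assert off["prior"] == pytest.approx(-0.5 * hyper.pi * delta**2, rel=1e-12)

    def test_matches_independent_term_by_term_oracle(self):
        """Data terms against scipy's multivariate-normal log-density summed
        over samples; Laplace term against an independently coded expected
        information (inv/slogdet path)."""
        rng = np.random.default_rng(21)
        m, d = 3, 17
        K = [np.eye(m), _rand_psd(m, rng), _rand_psd(m, rng, rank=1)]
        lam = np.array([0.3, -0.8, 0.5])
        hyper = HyperPrior(eta=-1.0, pi=0.5)
        Y = rng.standard_normal((m, d))
        F, parts = free_energy(Y, K, lam, hyper, return_parts=True)

        sigma = sum(np.exp(l) * k for l, k in zip(lam, K))
        data_oracle = stats.multivariate_normal(mean=np.zeros(m), cov=sigma).logpdf(Y.T).sum()
        assert parts["data"] == pytest.approx(data_oracle, rel=1e-9)

        Sinv = np.linalg.inv(sigma)
        n = len(K)
        info = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                info[i, j] = 0.5 * d * np.trace(
                    Sinv @ (np.exp(lam[i]) * K[i]) @ Sinv @ (np.exp(lam[j]) * K[j])
                )
        lap_oracle = 0.5 * (n * np.log(hyper.pi)
                            - np.linalg.slogdet(info + hyper.pi * np.eye(n))[1])
        assert parts["laplace"] == pytest.approx(lap_oracle, rel=1e-9)
        prior_oracle = -0.5 * hyper.pi * np.sum((lam - hyper.eta) ** 2)
        assert F == pytest.approx(data_oracle + lap_oracle + prior_oracle, rel=1e-9)

    def test_non_pd_sigma_raises(self):
        K = [np.array([[1.0, 2.0], [2.0, 1.0]])]  # indefinite
        with pytest.raises(np.linalg.LinAlgError):
            free_energy(np.zeros((2, 3)), K, [0.0])


class TestReMLEstimate:
    def test_default_hyperprior_is_shutoff_prior(self):
        hyper = HyperPrior()
        assert hyper.eta == -32.0
        assert hyper.variance == 256.0

    def test_free_energy_trace_never_decreases(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = int(rng.integers(2, 10))
            N = int(rng.integers(1, 4))
            d = int(rng.integers(2, 50))
            K = [np.eye(m)] + [_rand_psd(m, rng, rank=int(rng.integers(1, m + 1)))
                               for _ in range(N)]
            Y = rng.standard_normal((m, d)) * np.exp(rng.uniform(-2, 2))
            fit = reml_estimate(Y, K)
            assert np.all(np.diff(fit.F_trace) >= -1e-9)

    def test_generating_component_recovered(self):
        """Data drawn from one of two disjoint submap components: its fitted
        weight dwarfs the silent component's."""
        rng = np.random.default_rng(9)
        m, s, d = 12, 30, 200
        G = rng.standard_normal((m, s))
        pr = build_components([np.arange(0, 5), np.arange(10, 15)], s)
        noise = NoiseModel(C=np.eye(m))
        K = sensor_covariance_components(G, pr, noise)
        J = np.zeros((s, d))
        J[0:5] = 3.0 * rng.standard_normal((1, d))  # coherent patch activity
        Y = G @ J + 0.5 * rng.standard_normal((m, d))
        fit = reml_estimate(Y, K, priors=pr)
        w = fit.weights
        assert w[1] / w[2] > 10.0
        assert w[2] / w[1] < 1e-6

    def test_matches_grid_search_argmax(self):
        """Two-hyperparameter toy: the ReML optimum sits within one grid step
        of the exhaustive argmax of F over a 200×200 λ grid."""
        rng = np.random.default_rng(200)
        m, d = 6, 400
        C = np.eye(m)
        g = rng.standard_normal(m)
        K = np.outer(g, g) / m
        lam_true = np.array([rng.uniform(-1, 1), rng.uniform(0, 2)])
        Y = np.linalg.cholesky(np.exp(lam_true[0]) * C + np.exp(lam_true[1]) * K) \
            @ rng.standard_normal((m, d))
        fit = reml_estimate(Y, [C, K], tol=1e-8)
        grid = np.linspace(-36, 4, 200)
        best, arg = -np.inf, None
        for a in grid:
            for b in grid:
                try:
                    F = free_energy(Y, [C, K], [a, b])
                except np.linalg.LinAlgError:
                    F = -np.inf
                if F > best:
                    best, arg = F, (a, b)
        step = grid[1] - grid[0]
        assert abs(fit.mu_lambda[0] - arg[0]) <= step
        assert abs(fit.mu_lambda[1] - arg[1]) <= step

    def test_shrinkage_with_zero_data(self):
        """Y = 0 drives every source weight to (or below) the prior mean."""
        rng = np.random.default_rng(3)
        m = 6
        hyper = HyperPrior()
        K = [np.eye(m), _rand_psd(m, rng), _rand_psd(m, rng)]
        fit = reml_estimate(np.zeros((m, 8)), K, hyper)
        bound = np.exp(hyper.eta + 3.0 / np.sqrt(hyper.pi))
        assert np.all(fit.weights[1:] <= bound)
        assert np.all(fit.mu_lambda <= hyper.eta + 1e-6)

    def test_occam_penalty_bounded(self):
        """Adding a component whose generating weight is zero does not raise
        converged F by more than 0.5 nats on average over seeds."""
        rng = np.random.default_rng(77)
        m, d = 6, 120
        diffs = []
        for _ in range(100):
            C = np.eye(m)
            K1 = _rand_psd(m, rng, rank=2)
            K2 = _rand_psd(m, rng, rank=2)
            Y = np.linalg.cholesky(C + K1 + 1e-12 * np.eye(m)) @ rng.standard_normal((m, d))
            f2 = reml_estimate(Y, [C, K1]).F
            f3 = reml_estimate(Y, [C, K1, K2]).F
            diffs.append(f3 - f2)
        assert np.mean(diffs) <= 0.5

    def test_empty_or_zero_components_rejected(self):
        with pytest.raises(ValueError):
            reml_estimate(np.zeros((2, 3)), [])
        with pytest.raises(ValueError, match="zero"):
            reml_estimate(np.ones((2, 3)), [np.zeros((2, 2))])

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(0)
        m = 8
        K = [np.eye(m), _rand_psd(m, rng)]
        Y = rng.standard_normal((m, 50))
        with pytest.warns(UserWarning, match="did not converge"):
            fit = reml_estimate(Y, K, tol=0.0, max_iter=2)
        assert not fit.converged


class TestAssembleR:
    def test_prior_mean_switches_everything_off(self):
        pr = build_components([np.array([0, 1]), np.array([3])], 5)
        R = assemble_R(pr, np.full(2, -32.0))
        assert np.abs(R).max() <= np.exp(-32.0) * 1.0 + 1e-30

    def test_single_submap_scaling(self):
        pr = build_components([np.array([0, 1])], 3)
        R = assemble_R(pr, [np.log(2.0)])
        assert np.allclose(R[:2, :2], 2.0 * np.ones((2, 2)), rtol=1e-14)
        assert np.abs(R[2]).max() == 0.0

    def test_matches_dense_weighted_sum(self):
        rng = np.random.default_rng(13)
        subs = [np.array([0, 4, 7]), np.array([2, 3]), np.array([9])]
        for enc in ("indicator-rank1", "diagonal"):
            pr = build_components(subs, 10, encoding=enc)
            mu = rng.uniform(-3, 2, 3)
            R = assemble_R(pr, mu)
            dense = sum(np.exp(w) * c.dense(10) for w, c in zip(mu, pr.components))
            assert np.abs(R - dense).max() < 1e-12 * max(np.abs(dense).max(), 1.0)
            assert np.linalg.eigvalsh(R).min() >= -1e-12

    def test_linear_mode_rejects_negative_weights(self):
        pr = build_components([np.array([0])], 2)
        with pytest.raises(ValueError, match="non-negative"):
            assemble_R(pr, [-0.5], weight_scale="linear")
        R = assemble_R(pr, [0.5], weight_scale="linear")
        assert R[0, 0] == 0.5


class TestInverseSolution:
    def test_zero_data_zero_sources(self):
        rng = np.random.default_rng(0)
        G = rng.standard_normal((4, 9))
        J = inverse_solution(np.zeros((4, 6)), G, np.eye(9), np.eye(4), 0.1)
        assert np.abs(J).max() == 0.0

    def test_exact_inverse_limit_square_gain(self):
        rng = np.random.default_rng(8)
        G = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        Y = rng.standard_normal((5, 7))
        J = inverse_solution(Y, G, np.eye(5), np.eye(5), 1e-12)
        assert np.abs(J - np.linalg.solve(G, Y)).max() < 1e-8

    def test_matches_woodbury_dual_form(self):
        """Primal RGᵀ(GRGᵀ+λC)⁻¹Y vs dual (Gᵀ(λC)⁻¹G+R⁻¹)⁻¹Gᵀ(λC)⁻¹Y."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            m, s, d = 4, 6, 5
            G = rng.standard_normal((m, s))
            R = _rand_psd(s, rng) + 0.5 * np.eye(s)
            C = _rand_psd(m, rng) + 0.5 * np.eye(m)
            lam = float(rng.uniform(0.05, 2.0))
            Y = rng.standard_normal((m, d))
            J = inverse_solution(Y, G, R, C, lam)
            lamC_inv = np.linalg.inv(lam * C)
            dual = np.linalg.solve(
                G.T @ lamC_inv @ G + np.linalg.inv(R), G.T @ lamC_inv @ Y
            )
            scale = max(np.abs(J).max(), 1.0)
            assert np.abs(J - dual).max() / scale < 1e-8

    def test_true_prior_beats_mismatched_prior_in_mse(self):
        """The Gaussian-optimal linear estimate (true R, C) has lower mean
        squared source error than the same estimator with a wrong R."""
        rng = np.random.default_rng(23)
        m, s, d = 8, 14, 40
        G = rng.standard_normal((m, s))
        r_diag = np.where(np.arange(s) < 4, 4.0, 0.01)
        R_true = np.diag(r_diag)
        R_wrong = np.diag(r_diag[::-1].copy())
        C = np.eye(m)
        err_true = err_wrong = 0.0
        for _ in range(50):
            J = np.sqrt(r_diag)[:, None] * rng.standard_normal((s, d))
            Y = G @ J + rng.standard_normal((m, d))
            err_true += np.sum((inverse_solution(Y, G, R_true, C, 1.0) - J) ** 2)
            err_wrong += np.sum((inverse_solution(Y, G, R_wrong, C, 1.0) - J) ** 2)
        assert err_true < err_wrong

    def test_singular_system_raises_with_condition(self):
        G = np.zeros((3, 4))
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            inverse_solution(np.ones((3, 2)), G, np.eye(4), np.zeros((3, 3)), 1.0)
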