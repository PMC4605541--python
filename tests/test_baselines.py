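"""Exact-likelihood MAP, Gibbs imputation and Monte-Carlo EM baselines."""

import numpy as np
import pytest

import shotgun_conn as sc
from shotgun_conn.baselines import em_step, fit_map_full, full_loglik, gibbs_impute
from shotgun_conn.ell import Prior, fit_map, offdiag_nonzero_fraction
from shotgun_conn.moments import exact_moments, estimate_moments
from shotgun_conn.netsim import SpikeMatrix, logistic
from shotgun_conn.observer import ObservationMask, SchemeConfig, make_mask


class TestFullLoglik:
    def test_single_bernoulli_term(self):
        spikes = SpikeMatrix(S=np.array([[1]], dtype=np.uint8))
        val = full_loglik(np.zeros((1, 1)), np.zeros(1), spikes)
        assert val == pytest.approx(np.log(0.5))

    def test_uncoupled_unbiased_is_nt_log2(self):
        rng = np.random.default_rng(3)
        S = (rng.random((4, 200)) < 0.4).astype(np.uint8)
        val = full_loglik(np.zeros((4, 4)), np.zeros(4), SpikeMatrix(S=S))
        assert val == pytest.approx(-4 * 200 * np.log(2))

    def test_profile_ell_close_to_exact(self):
        # consistency of the approximation at the true parameters
        params = sc.generate_network(sc.NetworkGenConfig(N=3, seed=81))
        spikes = sc.simulate_glm(params, 100_000, seed=82)
        mom = exact_moments(spikes)
        exact = full_loglik(params.W, params.b, spikes) / spikes.T
        approx = sc.profile_ell(params.W, mom, spikes.T) / spikes.T
        assert approx == pytest.approx(exact, rel=0.02)


class TestFitMapFull:
    def test_huge_lambda_leaves_bias_only(self):
        params = sc.generate_network(sc.NetworkGenConfig(N=6, seed=83))
        spikes = sc.simulate_glm(params, 50_000, seed=84)
        res = fit_map_full(spikes, Prior(lam=10.0, penalize_diagonal=True))
        assert np.all(res.W_hat == 0)
        rate = spikes.S.mean(axis=1)
        assert np.allclose(res.b_hat, np.log(rate / (1 - rate)), atol=0.05)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        S = (rng.random((4, 300)) < 0.3).astype(np.uint8)
        spikes = SpikeMatrix(S=S)
        W = rng.normal(0, 0.4, (4, 4))
        b = rng.normal(0, 0.3, 4)
        base = full_loglik(W, b, spikes)
        eps = 1e-6
        for _ in range(8):
            i, j = rng.integers(0, 4, 2)
            E = np.zeros((4, 4))
            E[i, j] = eps
            fd = (full_loglik(W + E, b, spikes) - full_loglik(W - E, b, spikes)) / (2 * eps)
            # analytic gradient of the exact loglikelihood
            S_prev = np.concatenate([np.zeros((4, 1)), S[:, :-1]], axis=1).astype(float)
            U = W @ S_prev + b[:, None]
            G = (S - 1 / (1 + np.exp(-U))) @ S_prev.T
            assert abs(G[i, j] - fd) <= 1e-4 * max(1.0, abs(fd))

    def test_partial_mask_rejected(self):
        S = np.zeros((3, 10), dtype=np.uint8)
        O = np.ones_like(S)
        O[0, 0] = 0
        with pytest.raises(ValueError, match="ELL"):
            fit_map_full(SpikeMatrix(S=S), Prior(), mask=ObservationMask(O=O))

    def test_agrees_with_ell_fit_at_full_observation(self):
        params = sc.generate_network(sc.NetworkGenConfig(N=10, seed=85))
        spikes = sc.simulate_glm(params, 100_000, seed=86)
        mom = exact_moments(spikes)
        lam = 1e-3
        res_ell = fit_map(mom, spikes.T, Prior(lam=lam))
        res_full = fit_map_full(spikes, Prior(lam=lam), max_iter=2000)
        # sign agreement on the true support
        nz = params.W != 0
        agree = np.sign(res_ell.W_hat[nz]) == np.sign(res_full.W_hat[nz])
        assert agree.mean() >= 0.95
        c = np.corrcoef(res_ell.W_hat.ravel(), res_full.W_hat.ravel())[0, 1]
        assert c >= 0.9


class TestGibbsImpute:
    def test_all_observed_is_identity(self):
        rng = np.random.default_rng(8)
        S = (rng.random((3, 20)) < 0.3).astype(np.uint8)
        spikes = SpikeMatrix(S=S)
        out = gibbs_impute(spikes, ObservationMask(O=np.ones_like(S)),
                           np.zeros((3, 3)), np.zeros(3), sweeps=5, seed=1)
        assert np.array_equal(out.S, S)

    def test_uncoupled_conditional_is_sigmoid_of_bias(self):
        # W = 0: the full conditional of a missing entry is Bernoulli(sigma(b))
        b = np.array([-1.0])
        S = np.zeros((1, 3), dtype=np.uint8)
        O = np.ones_like(S)
        O[0, 1] = 0
        draws = [
            gibbs_impute(SpikeMatrix(S=S), ObservationMask(O=O),
                         np.zeros((1, 1)), b, sweeps=1, seed=k).S[0, 1]
            for k in range(3000)
        ]
        p = np.mean(draws)
        expect = logistic(-1.0)
        assert abs(p - expect) < 4 * np.sqrt(expect * (1 - expect) / 3000)

    def test_single_missing_entry_matches_enumeration(self):
        # 2-neuron, 3-bin instance: exact conditional by enumerating both
        # completions of the joint GLM likelihood
        W = np.array([[-0.5, 1.2], [0.8, -0.3]])
        b = np.array([-0.2, 0.1])
        S = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.uint8)
        O = np.ones_like(S)
        O[0, 1] = 0  # missing: neuron 0, middle bin

        def joint_loglik(S_full):
            total = 0.0
            for t in (1, 2):
                U = W @ S_full[:, t - 1] + b
                for i in range(2):
                    total += S_full[i, t] * U[i] - np.logaddexp(0.0, U[i])
            return total

        logp = []
        for s in (0, 1):
            Sc = S.copy().astype(float)
            Sc[0, 1] = s
            logp.append(joint_loglik(Sc))
        p1 = np.exp(logp[1]) / (np.exp(logp[0]) + np.exp(logp[1]))

        draws = [
            gibbs_impute(SpikeMatrix(S=S), ObservationMask(O=O), W, b,
                         sweeps=1, seed=k).S[0, 1]
            for k in range(4000)
        ]
        emp = np.mean(draws)
        assert abs(emp - p1) < 3 * np.sqrt(p1 * (1 - p1) / 4000)

    def test_stationary_distribution_chi_squared(self):
        # two missing entries: empirical completion frequencies vs exact
        # conditional, chi-squared test at alpha = 0.001
        from scipy.stats import chi2

        W = np.array([[-0.4, 0.9], [0.7, -0.2]])
        b = np.array([0.0, -0.3])
        S = np.array([[1, 0, 1], [0, 0, 1]], dtype=np.uint8)
        O = np.ones_like(S)
        O[0, 1] = 0
        O[1, 1] = 0

        def joint_loglik(S_full):
            total = 0.0
            for t in (1, 2):
                U = W @ S_full[:, t - 1] + b
                for i in range(2):
                    total += S_full[i, t] * U[i] - np.logaddexp(0.0, U[i])
            return total

        states = [(0, 0), (0, 1), (1, 0), (1, 1)]
        logp = []
        for sa, sb in states:
            Sc = S.astype(float).copy()
            Sc[0, 1], Sc[1, 1] = sa, sb
            logp.append(joint_loglik(Sc))
        pr = np.exp(logp - np.logaddexp.reduce(logp))

        n_runs = 4000
        counts = np.zeros(4)
        for k in range(n_runs):
            out = gibbs_impute(SpikeMatrix(S=S), ObservationMask(O=O), W, b,
                               sweeps=20, seed=k).S
            counts[states.index((out[0, 1], out[1, 1]))] += 1
        expected = pr * n_runs
        stat = ((counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.999, df=3)


class TestEMStep:
    def test_full_observation_is_fixed_point(self):
        params = sc.generate_network(sc.NetworkGenConfig(N=8, seed=91))
        spikes = sc.simulate_glm(params, 60_000, seed=92)
        mask = ObservationMask(O=np.ones_like(spikes.S))
        mom = estimate_moments(spikes, mask)
        res = fit_map(mom, spikes.T, Prior(lam=1e-3))
        res2 = em_step(spikes, mask, res, Prior(lam=1e-3), seed=93)
        assert np.abs(res2.W_hat - res.W_hat).max() < 1e-3
        assert np.isfinite(res2.objective_trace).all()

    def test_em_runs_on_partial_data(self):
        params = sc.generate_network(sc.NetworkGenConfig(N=10, seed=94))
        spikes = sc.simulate_glm(params, 20_000, seed=95)
        mask = make_mask(SchemeConfig(scheme="fully_random", seed=96),
                         10, spikes.T, 0.5)
        mom = estimate_moments(spikes, mask)
        res = fit_map(mom, spikes.T, Prior(lam=1e-3))
        res2 = em_step(spikes, mask, res, Prior(lam=1e-3), seed=97)
        assert res2.W_hat.shape == (10, 10)
        assert np.isfinite(res2.W_hat).all()
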