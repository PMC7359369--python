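"""MCMC engine: priors, elementary moves, sweeps, and chain plumbing."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from gpgrn import (
    HyperState,
    PriorSpec,
    SamplerConfig,
    Series,
    TimeSeriesDataset,
    concatenate,
    confidence_matrix,
    log_prior,
    mh_step,
    prior_link_probability,
    propose_indicator_flip,
    run_mcmc,
)
from gpgrn.sampler import (
    MCMCChain,
    Posterior,
    _batched_factors,
    _lr_batched_factors,
    _lr_factor,
    _lr_scaled_factor,
    _lr_traj_factor,
    cn_propose_trajectory,
    initial_trajectories,
)
from gpgrn.trajectory import log_trajectory_prior


def _tiny_assembly(n=2, M=7, refine=2, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(float(M + 1))
    Y = rng.normal(size=(M + 1, n)) * 0.3 + 0.5
    ds = TimeSeriesDataset([Series(times, Y)], [f"g{i+1}" for i in range(n)])
    return concatenate(ds, refine=refine)


class TestLogPrior:
    def test_eta_one_topology_term_vanishes(self):
        spec = PriorSpec()
        h0 = HyperState.initial(2, eta=1.0)
        h1 = h0.copy()
        h1.S[0, 1] = 1
        # identical continuous parameters: difference is the S term only
        assert log_prior(h1, spec) == pytest.approx(log_prior(h0, spec), abs=1e-12)

    def test_extra_link_changes_prior_by_log_eta(self):
        # The slab magnitude H is part of the state whether or not the link is
        # active, and its exponential factor is carried permanently
        # (pseudo-prior convention), so one extra link costs exactly log(eta).
        spec = PriorSpec()
        eta = 0.4
        h0 = HyperState.initial(3, eta=eta)
        h1 = h0.copy()
        h1.S[1, 2] = 1
        assert log_prior(h1, spec) - log_prior(h0, spec) == pytest.approx(math.log(eta))

    def test_out_of_support_returns_neg_inf(self):
        spec = PriorSpec()
        bad = SimpleNamespace(
            S=np.zeros((1, 1), int), H=np.ones((1, 1)), gamma=np.ones(1),
            q=np.ones(1), r=np.ones(1), a=np.array([-0.1]), b=np.ones(1), eta=1.0,
        )
        assert log_prior(bad, spec) == -np.inf


class TestPriorLinkProbability:
    @pytest.mark.parametrize("eta,want", [(1.0, 0.5), (0.0, 0.0), (1 / 3, 0.25)])
    def test_values(self, eta, want):
        assert prior_link_probability(eta) == pytest.approx(want)


class TestMhStep:
    def test_neg_inf_always_rejects(self):
        rng = np.random.default_rng(0)
        assert not any(mh_step(0.0, -np.inf, 0.0, rng) for _ in range(100))

    def test_large_gain_always_accepts(self):
        rng = np.random.default_rng(1)
        assert all(mh_step(0.0, 10.0, 0.0, rng) for _ in range(100))

    def test_acceptance_rate_half(self):
        rng = np.random.default_rng(2)
        n = 100_000
        acc = sum(mh_step(0.0, -math.log(2.0), 0.0, rng) for _ in range(n))
        assert abs(acc / n - 0.5) < 0.01

    def test_nan_rejects_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning):
            assert not mh_step(0.0, float("nan"), 0.0, rng)


class TestProposeIndicatorFlip:
    def test_zero_row_gains_one_link(self):
        rng = np.random.default_rng(0)
        S = np.zeros((3, 3), int)
        row, col = propose_indicator_flip(S, 0, rng)
        assert row.sum() == 1 and row[col] == 1

    def test_involution(self):
        rng = np.random.default_rng(1)
        S = np.array([[1, 0, 1]])
        row1, col = propose_indicator_flip(S, 0, rng)
        S2 = S.copy()
        S2[0] = row1
        row2 = S2[0].copy()
        row2[col] = 1 - row2[col]
        assert np.array_equal(row2, S[0])

    def test_column_uniformity(self):
        rng = np.random.default_rng(2)
        S = np.zeros((1, 4), int)
        counts = np.zeros(4)
        for _ in range(10_000):
            _, col = propose_indicator_flip(S, 0, rng)
            counts[col] += 1
        assert np.all(np.abs(counts - 2500) < 150)


class TestCnProposal:
    def test_zero_step_is_identity(self):
        asm = _tiny_assembly()
        trajs = initial_trajectories(asm)
        rng = np.random.default_rng(0)
        prop = cn_propose_trajectory(trajs, np.full(2, 0.1), 0.0, rng)
        assert np.allclose(prop[0].values, trajs[0].values, atol=1e-14)

    def test_initial_state_fixed(self):
        asm = _tiny_assembly()
        trajs = initial_trajectories(asm)
        rng = np.random.default_rng(1)
        prop = cn_propose_trajectory(trajs, np.full(2, 0.1), 0.5, rng)
        assert np.array_equal(prop[0].values[0], trajs[0].values[0])
        assert not np.allclose(prop[0].values[1:], trajs[0].values[1:])

    def test_same_rng_state_same_proposal(self):
        asm = _tiny_assembly()
        trajs = initial_trajectories(asm)
        a = cn_propose_trajectory(trajs, np.full(2, 0.1), 0.3, np.random.default_rng(7))
        b = cn_propose_trajectory(trajs, np.full(2, 0.1), 0.3, np.random.default_rng(7))
        assert np.array_equal(a[0].values, b[0].values)


class TestConfidenceMatrix:
    def test_identical_samples(self):
        S = np.array([[0, 1], [1, 0]])
        cm = confidence_matrix(np.array([S, S, S]))
        assert np.array_equal(cm.probs, S)

    def test_two_sample_average(self):
        a = np.zeros((1, 2), int)
        b = np.zeros((1, 2), int)
        b[0, 1] = 1
        cm = confidence_matrix(np.array([a, b]))
        assert cm.probs[0, 1] == 0.5
        assert cm.n_samples == 2

    def test_bernoulli_law_of_large_numbers(self):
        rng = np.random.default_rng(0)
        samples = (rng.uniform(size=(1000, 1, 1)) < 0.3).astype(int)
        cm = confidence_matrix(samples)
        assert abs(cm.probs[0, 0] - 0.3) < 0.05


class TestPosteriorFactors:
    def test_batched_matches_per_gene(self):
        asm = _tiny_assembly(n=3, M=6)
        cfg = SamplerConfig(n_iter=10, burn_in=1)
        post = Posterior(asm, cfg)
        post.set_trajs(initial_trajectories(asm))
        rng = np.random.default_rng(0)
        hyper = HyperState(
            S=rng.integers(0, 2, size=(3, 3)), H=rng.uniform(0.2, 1.5, size=(3, 3)),
            gamma=rng.uniform(0.5, 2, 3), q=rng.uniform(0.05, 0.5, 3),
            r=np.full(3, 0.1), a=rng.uniform(0, 1, 3), b=rng.uniform(0, 1, 3),
        )
        batched, _ = _batched_factors(post, hyper)
        per_gene = np.array([post.gene_factor(i, hyper) for i in range(3)])
        assert np.allclose(batched, per_gene, atol=1e-10)

    def test_updating_one_gene_leaves_others_bit_identical(self):
        asm = _tiny_assembly(n=3, M=6)
        cfg = SamplerConfig(n_iter=10, burn_in=1, seed=0)
        chain = MCMCChain(asm, cfg, np.random.default_rng(0))
        before = chain.prior_f.copy()
        for _ in range(20):
            chain._update_scale(1, "gamma")
            chain._update_h(1, 0) if chain.hyper.S[1, 0] else chain._update_indicator(1)
        assert chain.prior_f[0] == before[0]
        assert chain.prior_f[2] == before[2]

    def test_beta_consistency_during_sweeps(self):
        asm = _tiny_assembly(n=2, M=6)
        cfg = SamplerConfig(n_iter=10, burn_in=1, seed=0)
        chain = MCMCChain(asm, cfg, np.random.default_rng(0))
        for _ in range(10):
            chain.sweep()
            fresh, _ = _batched_factors(chain.post, chain.hyper)
            assert np.allclose(fresh, chain.prior_f, atol=1e-9)
            assert np.array_equal(chain.hyper.beta, chain.hyper.S * chain.hyper.H)


class TestLowRankFactors:
    """The pseudo-input fast path used automatically on large grids."""

    def _chain(self, M, n=2, seed=0, n_iter=10):
        asm = _tiny_assembly(n=n, M=M, refine=2, seed=seed)
        cfg = SamplerConfig(n_iter=n_iter, burn_in=1, seed=seed)
        return MCMCChain(asm, cfg, np.random.default_rng(seed))

    def test_auto_resolution(self):
        # 7 intervals x refine 2 = 14 increments: exact density
        assert self._chain(M=7).post.pseudo is None
        # 40 intervals x refine 2 = 80 increments: low-rank with 32 points
        chain = self._chain(M=40)
        assert chain.post.fast_lowrank
        assert chain.post.pseudo.points.shape[0] == 32

    def test_batched_matches_slow_reference_at_init(self):
        # at the empty-topology start the kernel is near-constant, so the
        # pseudo-point Gram matrix is near rank one (condition ~ m/jitter);
        # equivalent arithmetic orderings then differ at the 1e-5 level
        chain = self._chain(M=40)
        want = log_trajectory_prior(chain.trajs[0], chain.hyper,
                                    pseudo=chain.post.pseudo)
        assert float(np.sum(chain.prior_f)) == pytest.approx(want, abs=1e-4)

    def test_cached_factors_track_slow_reference_during_sweeps(self):
        chain = self._chain(M=40)
        for _ in range(5):
            chain.sweep()
        # the cached factors and a cache-free batched rebuild agree to
        # roundoff; the independent slow evaluation agrees up to the
        # conditioning of the near-rank-one pseudo-point Gram matrix
        fresh, _ = _lr_batched_factors(chain.post, chain.hyper)
        assert np.allclose(fresh, chain.prior_f, atol=1e-6)
        want = log_trajectory_prior(chain.trajs[0], chain.hyper,
                                    pseudo=chain.post.pseudo)
        assert float(np.sum(chain.prior_f)) == pytest.approx(want, abs=1e-3)

    def test_scaled_and_trajectory_reuse_match_full_factor(self):
        # well-conditioned synthetic kernel pieces isolate the algebraic
        # identities (exact gamma scaling; unchanged pseudo-point factors)
        # from the near-rank-one conditioning of empty-topology states
        rng = np.random.default_rng(3)
        N, m, dim = 90, 30, 3
        dt = rng.uniform(0.05, 0.2, N)
        Z = rng.normal(size=(N, dim))
        P = Z[rng.choice(N, m, replace=False)]
        beta = rng.uniform(0.3, 1.0, dim)

        def shapes(rows):
            return np.exp(-((rows[:, None, :] - P[None, :, :]) ** 2 @ beta))

        Enm, Emm = shapes(Z), shapes(P)
        resid = rng.normal(size=N)
        full0, c = _lr_factor(dt, Enm, Emm, 1.2, 0.05, resid)
        gamma, q = 2.7 * 1.2, 0.6 * 0.05
        full, _ = _lr_factor(dt, Enm, Emm, gamma, q, resid)
        scaled, _ = _lr_scaled_factor(dt, c, gamma, q)
        assert scaled == pytest.approx(full, abs=1e-6)
        Z2 = Z + 0.1 * rng.normal(size=Z.shape)
        Enm2 = shapes(Z2)
        resid2 = resid + 0.01 * rng.normal(size=N)
        full2, _ = _lr_factor(dt, Enm2, Emm, 1.2, 0.05, resid2)
        reused, _ = _lr_traj_factor(dt, Enm2, c, 1.2, 0.05, resid2)
        assert reused == full2  # bitwise: same factors, same arithmetic

    def test_large_grid_chain_deterministic(self):
        runs = []
        for _ in range(2):
            chain = self._chain(M=40, n_iter=20)
            for _ in range(15):
                chain.sweep()
            runs.append((chain.hyper.S.copy(), chain.prior_f.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestGibbsSweep:
    def test_smoke_no_nan(self):
        asm = _tiny_assembly(n=2, M=5)
        cfg = SamplerConfig(n_iter=10, burn_in=1, seed=0)
        chain = MCMCChain(asm, cfg, np.random.default_rng(0))
        for _ in range(5):
            chain.sweep()
            assert np.isfinite(chain.log_posterior)

    def test_conjugate_q_recovery(self):
        # With S empty and gamma pinned near zero the model is a
        # linear-Gaussian random walk with drift b - a x; the q block's
        # stationary distribution is the analytic inverse-Gamma conditional.
        rng = np.random.default_rng(0)
        M, q_true = 200, 0.5
        times = np.arange(float(M + 1))
        x = np.zeros(M + 1)
        a_true, b_true = 0.5, 0.25
        for k in range(M):
            x[k + 1] = x[k] + (b_true - a_true * x[k]) + rng.normal() * math.sqrt(q_true)
        ds = TimeSeriesDataset([Series(times, x[:, None])], ["g1"])
        asm = concatenate(ds, refine=1)
        cfg = SamplerConfig(n_iter=10, burn_in=1, seed=0, adapt_cn=False, refine=1)
        means = []
        for c in range(10):
            chain = MCMCChain(
                asm, cfg, np.random.default_rng(100 + c), update_trajectory=False
            )
            chain.hyper.gamma[:] = 1e-12
            chain.hyper.a[:] = a_true
            chain.hyper.b[:] = b_true
            chain._sync()
            draws = []
            for it in range(1500):
                chain._update_scale(0, "q")
                if it >= 500:
                    draws.append(chain.hyper.q[0])
            means.append(np.mean(draws))
        assert abs(np.mean(means) - q_true) / q_true < 0.2

    def test_prior_only_link_frequency_smoke(self):
        asm = _tiny_assembly(n=2, M=5)
        cfg = SamplerConfig(n_iter=10, burn_in=1, eta=1.0)
        chain = MCMCChain(asm, cfg, np.random.default_rng(1), prior_only=True)
        freq = np.zeros_like(chain.hyper.S, dtype=float)
        n_sweeps = 4000
        for _ in range(n_sweeps):
            chain.sweep()
            freq += chain.hyper.S
        assert abs(freq.mean() / n_sweeps - 0.5) < 0.05


class TestRunMcmc:
    def _dataset(self, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(6.0)
        Y = rng.normal(size=(6, 2)) * 0.2 + 0.5
        return TimeSeriesDataset([Series(times, Y)], ["g1", "g2"])

    def test_single_sample_when_run_length_is_one(self):
        ds = self._dataset()
        cfg = SamplerConfig(n_iter=3, burn_in=2, thin=1, seed=0)
        store = run_mcmc(ds, cfg)
        assert store.S_samples.shape[0] == 1

    def test_determinism(self):
        ds = self._dataset()
        cfg = SamplerConfig(n_iter=30, burn_in=10, thin=5, seed=3)
        s1 = run_mcmc(ds, cfg)
        s2 = run_mcmc(ds, cfg)
        assert np.array_equal(s1.S_samples, s2.S_samples)

    def test_two_chains_pool_samples(self):
        ds = self._dataset()
        cfg = SamplerConfig(n_iter=12, burn_in=2, thin=5, seed=0, n_chains=2)
        store = run_mcmc(ds, cfg)
        assert store.S_samples.shape[0] == 4  # 2 per chain
        assert set(store.chain_ids.tolist()) == {0, 1}

    def test_store_round_trip(self, tmp_path):
        ds = self._dataset()
        cfg = SamplerConfig(n_iter=12, burn_in=2, thin=5, seed=0)
        store = run_mcmc(ds, cfg)
        out = str(tmp_path / "run")
        store.save(out)
        import json
        import os

        assert os.path.exists(os.path.join(out, "run_manifest.json"))
        meta = json.load(open(os.path.join(out, "run_manifest.json")))
        assert meta["n_samples"] == store.S_samples.shape[0]
        cm = store.confidence()
        assert cm.probs.shape == (2, 2)
        assert np.all((cm.probs >= 0) & (cm.probs <= 1))
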