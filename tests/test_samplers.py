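"""ACHR iterate and the three chain policies."""

import numpy as np
import pytest

from fluxsampler import (
    ChainState,
    SamplerConfig,
    SolutionSpace,
    achr_step,
    minmax_warmup,
    pull_to_interior,
    sample_gp,
    sample_hr,
    sample_optgp,
)
from fluxsampler.samplers import (
    ConfigurationError,
    DegeneratePoolError,
    _chain_sample_counts,
    _gp_warmup,
    _run_optgp_chain,
)
from fluxsampler.synthetic import (
    make_anisotropic_slab,
    make_box,
    make_triangle,
    rejection_sample,
)


def _state_1d(space, rng):
    pool = np.array([[0.0], [1.0]])
    return ChainState(
        current=np.array([0.5]),
        center=np.array([0.5]),
        iterate_count=2,
        pool=pool,
        pool_count=2,
        rng=rng,
    )


class TestAchrStep:
    def test_interval_mean_matches_uniform(self, rng):
        """On [0, 1] with pool {0, 1} the iterates are uniform steps whose
        long-run mean is 1/2."""
        space = SolutionSpace(make_box(1, 0.0, 1.0))
        state = _state_1d(space, rng)
        xs = np.empty(10_000)
        for i in range(xs.size):
            achr_step(space, state)
            xs[i] = state.current[0]
        se = xs.std() / np.sqrt(xs.size)
        # Autocorrelated chain: allow a generous multiple of the i.i.d. SE.
        assert abs(xs.mean() - 0.5) < 15 * se
        assert xs.min() >= 0.0 and xs.max() <= 1.0

    def test_collapsed_pool_raises(self, rng):
        space = SolutionSpace(make_box(1, 0.0, 1.0))
        state = ChainState(
            current=np.array([0.5]),
            center=np.array([0.5]),
            iterate_count=1,
            pool=np.array([[0.5]]),
            pool_count=1,
            rng=rng,
        )
        with pytest.raises(DegeneratePoolError):
            achr_step(space, state)

    def test_fixed_seed_reproduces_trajectory(self):
        space = SolutionSpace(make_box(2, -1.0, 1.0))
        trajs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            state = ChainState(
                current=np.zeros(2),
                center=np.zeros(2),
                iterate_count=4,
                pool=np.array([[-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]]),
                pool_count=4,
                rng=rng,
            )
            trajs.append(
                np.array([achr_step(space, state).current.copy() for _ in range(50)])
            )
        np.testing.assert_array_equal(trajs[0], trajs[1])

    def test_compiled_kernel_matches_reference_step(self, network_space):
        """The compiled optgp chain and the pure-Python iterate consume the
        same random stream and agree to round-off."""
        warm = pull_to_interior(minmax_warmup(network_space), 0.5)
        seed_seq = np.random.SeedSequence(4242)
        kernel_out = _run_optgp_chain(network_space, warm.points, 10, 20, seed_seq)

        rng = np.random.default_rng(seed_seq)
        w = warm.n_points
        pool = np.empty((w + 10, network_space.n))
        pool[:w] = warm.points
        idx0 = min(int(rng.random() * w), w - 1)
        state = ChainState(
            current=warm.points[idx0].copy(),
            center=warm.points.mean(axis=0),
            iterate_count=w,
            pool=pool,
            pool_count=w,
            rng=rng,
        )
        ref = np.empty((10, network_space.n))
        it = 0
        for s in range(10):
            for _ in range(20):
                achr_step(network_space, state)
                it += 1
                if it % 100 == 0:
                    state.current = network_space.correct_drift(state.current)
            state.current = network_space.correct_drift(state.current)
            ref[s] = state.current
            pool[state.pool_count] = state.current
            state.pool_count += 1
        np.testing.assert_allclose(kernel_out, ref, atol=1e-10)


class TestOptGp:
    def test_sample_allocation(self):
        assert _chain_sample_counts(100, 4) == [25, 25, 25, 25]
        assert _chain_sample_counts(10, 3) == [4, 3, 3]

    def test_chain_major_bookkeeping(self, network_space):
        cfg = SamplerConfig(n_samples=10, step_count=5, n_chains=3, seed=7)
        sm = sample_optgp(network_space, cfg)
        assert sm.samples.shape == (10, network_space.n)
        assert sm.meta["chain_sample_counts"] == [4, 3, 3]
        assert sm.meta["sampler"] == "optgp"

    def test_too_few_samples_for_chains_rejected(self):
        with pytest.raises(ConfigurationError):
            SamplerConfig(n_samples=2, step_count=5, n_chains=4)

    def test_every_sample_feasible(self, network_space):
        cfg = SamplerConfig(n_samples=500, step_count=20, n_chains=4, seed=3)
        sm = sample_optgp(network_space, cfg)
        for row in sm.samples:
            assert network_space.is_feasible(row).feasible

    def test_worker_count_does_not_change_output(self, network_space):
        cfg = SamplerConfig(n_samples=40, step_count=10, n_chains=4, seed=5)
        seq = sample_optgp(network_space, cfg, workers=1)
        par = sample_optgp(network_space, cfg, workers=2)
        np.testing.assert_array_equal(seq.samples, par.samples)


class TestGp:
    def test_zero_steps_returns_pulled_warmup(self, network_space):
        cfg = SamplerConfig(n_samples=20, step_count=0, seed=1, mode="gp")
        sm = sample_gp(network_space, cfg)
        warm = pull_to_interior(minmax_warmup(network_space), 0.5)
        np.testing.assert_allclose(sm.samples, warm.points)

    def test_no_random_weight_lps_when_n_equals_2n(self, network_space):
        warm = _gp_warmup(network_space, 2 * network_space.n, np.random.default_rng(0))
        assert set(warm.origin) == {"minmax"}
        warm_more = _gp_warmup(network_space, 2 * network_space.n + 3, np.random.default_rng(0))
        assert warm_more.origin.count("random_weight") == 3

    def test_end_points_feasible_and_deterministic(self, network_space):
        cfg = SamplerConfig(n_samples=15, step_count=30, seed=2, mode="gp")
        a = sample_gp(network_space, cfg)
        b = sample_gp(network_space, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        for row in a.samples:
            assert network_space.is_feasible(row).feasible


class TestHitAndRun:
    def test_box_marginals_pass_ks_uniformity(self):
        from scipy.stats import kstest

        space = SolutionSpace(make_box(3, 0.0, 1.0))
        sm = sample_hr(space, 10_000, thin=3, seed=17)
        for j in range(3):
            assert kstest(sm.samples[:, j], "uniform").statistic < 0.025

    def test_interval_mean(self):
        space = SolutionSpace(make_box(1, 0.0, 1.0))
        sm = sample_hr(space, 10_000, thin=1, seed=8)
        se = sm.samples.std() / 100.0
        assert abs(sm.samples.mean() - 0.5) < 10 * se

    def test_triangle_centroid_matches_rejection_oracle(self, triangle_space, rng):
        hr = sample_hr(triangle_space, 4000, thin=20, seed=13)
        oracle = rejection_sample(triangle_space, 8000, rng)
        se = np.sqrt(
            hr.samples.var(axis=0) / hr.n_samples
            + oracle.samples.var(axis=0) / oracle.n_samples
        )
        # 3x the combined SE, inflated 3x for residual autocorrelation.
        gap = np.abs(hr.samples.mean(axis=0) - oracle.samples.mean(axis=0))
        assert np.all(gap < np.maximum(9.0 * se, 0.01))
        np.testing.assert_allclose(hr.samples.mean(axis=0)[:2], [1 / 3, 1 / 3], atol=0.02)

    def test_invalid_parameters_rejected(self, triangle_space):
        with pytest.raises(ConfigurationError):
            sample_hr(triangle_space, 0)
        with pytest.raises(ConfigurationError):
            sample_hr(triangle_space, 10, thin=0)


def test_mixing_improves_with_step_count():
    """Self-deviation of the optgp sampler decreases with step count on an
    anisotropic polytope (one inversion allowed across the grid)."""
    from fluxsampler.deviation import RunSet, xy_deviation

    space = SolutionSpace(make_anisotropic_slab(4, aspect=100.0))
    devs = []
    for st in (1, 10, 100):
        runs = [
            sample_optgp(space, SamplerConfig(n_samples=200, step_count=st, n_chains=4, seed=s))
            for s in range(4)
        ]
        rs = RunSet.from_space(space, runs)
        devs.append(xy_deviation(rs, rs).xy_deviation)
    inversions = sum(devs[i + 1] > devs[i] for i in range(len(devs) - 1))
    assert inversions <= 1
    assert devs[-1] < devs[0]
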