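"""Sampler correctness: determinism, equilibrium, relabeling, diagnostics."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats

from rwmix import (
    MCMCConfig,
    MeanProcessSpec,
    ModelSpec,
    ParameterState,
    TimeSeriesMatrix,
    chain_diagnostics,
    chain_from_csv,
    chain_to_csv,
    initialize_state,
    posterior_median,
    relabel_chain,
    sample_posterior,
    simulate_doubly_stochastic,
)
from rwmix.sampler import PosteriorChain
from rwmix.simulate import permutation_matched_mse


def _conjugate_setup(seed=7, n=50):
    """K = 1, free centre vector only: a linear-Gaussian conjugate model."""
    rng = np.random.default_rng(seed)
    s2, z0, e = 0.5, 0.0, 0.8
    X = TimeSeriesMatrix(np.array([1.0, 1.5]) + rng.normal(0, math.sqrt(s2), (n, 2)))
    spec = ModelSpec(
        K=1,
        mean_process=MeanProcessSpec(eps2=(e,)),
        fixed_z0=(z0,),
        fixed_sigma2=(s2,),
        fixed_weights=(1.0,),
    )
    V0 = np.array([[e, e], [e, 2 * e]])
    m0 = np.array([z0, z0])
    Vp = np.linalg.inv(np.linalg.inv(V0) + n / s2 * np.eye(2))
    mp = Vp @ (np.linalg.inv(V0) @ m0 + n / s2 * X.values.mean(axis=0))
    return X, spec, mp, Vp


class TestInitializeState:
    def test_k1_center_is_column_mean(self, rng):
        X = TimeSeriesMatrix(rng.normal(size=(12, 5)))
        state = initialize_state(X, ModelSpec(K=1), seed=0)
        np.testing.assert_allclose(state.centers[0], X.values.mean(axis=0))

    def test_deterministic(self, rng):
        X = TimeSeriesMatrix(rng.normal(size=(10, 4)))
        a = initialize_state(X, ModelSpec(K=3), seed=5)
        b = initialize_state(X, ModelSpec(K=3), seed=5)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_separated_clusters_found(self, flat_clusters):
        X, _ = flat_clusters
        state = initialize_state(X, ModelSpec(K=3), seed=0)
        levels = np.sort(state.centers.mean(axis=1))
        np.testing.assert_allclose(levels, [-5.0, 0.0, 5.0], atol=1.0)

    def test_k_larger_than_n_rejected(self, rng):
        X = TimeSeriesMatrix(rng.normal(size=(2, 4)))
        with pytest.raises(ValueError):
            initialize_state(X, ModelSpec(K=3), seed=0)


class TestSamplePosterior:
    def test_flat_center_recovery(self):
        ds = simulate_doubly_stochastic(
            ModelSpec(K=1), z0=2.0, eps2=1e-12, sigma2=0.25,
            weights=[1.0], n=40, d=8, seed=3,
        )
        spec = ModelSpec.for_data(ds.data, K=1, eps2=0.05)
        chain = sample_posterior(ds.data, spec, MCMCConfig(seed=1))
        med = posterior_median(chain)
        centers = chain.stacked("centers")[:, 0, :]
        sd = centers.std(axis=0)
        assert np.all(np.abs(med.centers[0] - 2.0) < 3 * sd + 1e-9)
        assert np.all(np.abs(med.centers[0] - 2.0) < 0.2)

    def test_prior_only_sigma2_matches_prior(self):
        rng = np.random.default_rng(0)
        X = TimeSeriesMatrix(rng.normal(0, 1, (10, 4)))
        spec = ModelSpec(
            K=1,
            fixed_centers=[[0.0] * 4],
            fixed_z0=(0.0,),
            fixed_weights=(1.0,),
        )
        cfg = MCMCConfig(n_warmup=1000, n_samples=4000, seed=5, prior_only=True)
        chain = sample_posterior(X, spec, cfg)
        s2 = chain.stacked("sigma2")[:, 0]
        # half-Cauchy(1) on sigma => CDF of sigma^2 is (2/pi) atan(sqrt(v))
        ks = stats.kstest(s2, lambda v: 2 / math.pi * np.arctan(np.sqrt(v)))
        assert ks.statistic < 0.05

    def test_same_seed_identical_chains(self, rng):
        X = TimeSeriesMatrix(rng.normal(size=(8, 4)))
        spec = ModelSpec.for_data(X, K=2)
        cfg = MCMCConfig(n_warmup=50, n_samples=50, seed=42)
        a = sample_posterior(X, spec, cfg)
        b = sample_posterior(X, spec, cfg)
        np.testing.assert_array_equal(
            a.log_posterior_values, b.log_posterior_values
        )
        np.testing.assert_array_equal(a.stacked("centers"), b.stacked("centers"))

    def test_conjugate_equilibrium(self):
        X, spec, mp, Vp = _conjugate_setup()
        chain = sample_posterior(
            X, spec, MCMCConfig(n_warmup=1000, n_samples=5000, seed=3)
        )
        z1 = chain.stacked("centers")[:, 0, 0]
        ks = stats.kstest(
            z1, lambda v: stats.norm.cdf(v, mp[0], math.sqrt(Vp[0, 0]))
        )
        assert ks.statistic < 0.05

    def test_two_component_recovery(self):
        ds = simulate_doubly_stochastic(
            ModelSpec(K=2), z0=[-3.0, 3.0], eps2=0.05, sigma2=0.25,
            weights=[0.5, 0.5], n=60, d=10, seed=9,
        )
        spec = ModelSpec.for_data(ds.data, K=2, eps2=0.05)
        chain = relabel_chain(sample_posterior(ds.data, spec, MCMCConfig(seed=2)))
        med = posterior_median(chain)
        mse, _ = permutation_matched_mse(med.centers, ds.true_centers)
        assert mse <= 0.05


class TestRelabel:
    def _fixed_chain(self, rng, K=3, d=4, n_draws=30):
        base = ParameterState(
            weights=np.array([0.5, 0.3, 0.2]),
            centers=rng.normal(scale=5.0, size=(K, d)),
            sigma2=np.array([1.0, 2.0, 3.0]),
            z0=np.array([0.0, 1.0, 2.0]),
        )
        return base

    def test_no_switching_is_identity(self, rng):
        base = self._fixed_chain(rng)
        draws = [base] * 20
        chain = PosteriorChain(draws, np.zeros(20), ModelSpec(K=3), MCMCConfig(seed=0))
        out = relabel_chain(chain)
        for st in out.draws:
            np.testing.assert_array_equal(st.centers, base.centers)

    def test_forced_recovery_from_permutations(self, rng):
        base = self._fixed_chain(rng)
        perms = [rng.permutation(3) for _ in range(25)]
        draws = [base] + [base.permuted(p) for p in perms]
        chain = PosteriorChain(
            draws, np.zeros(len(draws)), ModelSpec(K=3), MCMCConfig(seed=0)
        )
        out = relabel_chain(chain)
        for st in out.draws:
            np.testing.assert_array_equal(st.centers, base.centers)
            np.testing.assert_array_equal(st.weights, base.weights)

    def test_matches_exhaustive_permutation_search(self, rng):
        # noisy draws with injected permutations; oracle = brute force over 3!
        K, d = 3, 4
        base = self._fixed_chain(rng)
        draws = []
        for _ in range(40):
            noisy = ParameterState(
                base.weights,
                base.centers + rng.normal(scale=0.05, size=(K, d)),
                base.sigma2,
                base.z0,
            )
            draws.append(noisy.permuted(rng.permutation(K)))
        chain = PosteriorChain(
            draws, rng.normal(size=40), ModelSpec(K=3), MCMCConfig(seed=0)
        )
        out = relabel_chain(chain)
        # oracle: same running-mean reference, but brute force over all 3! perms
        ref = chain.draws[0].centers.astype(float).copy()
        for i, (st_in, st_out) in enumerate(zip(chain.draws, out.draws)):
            best = min(
                itertools.permutations(range(K)),
                key=lambda p: ((st_in.centers[list(p)] - ref) ** 2).sum(),
            )
            np.testing.assert_allclose(st_out.centers, st_in.centers[list(best)])
            ref += (st_out.centers - ref) / (i + 1)
        # all relabeled draws now share one component ordering
        spread = np.stack([d.centers for d in out.draws]).std(axis=0)
        assert spread.max() < 0.5
        np.testing.assert_array_equal(
            out.log_posterior_values, chain.log_posterior_values
        )


class TestPosteriorMedian:
    def test_identical_draws_returned(self, rng):
        st = ParameterState([1.0], rng.normal(size=(1, 4)), [1.0], [0.0])
        chain = PosteriorChain([st] * 5, np.zeros(5), ModelSpec(K=1), MCMCConfig(seed=0))
        med = posterior_median(chain)
        np.testing.assert_allclose(med.centers, st.centers)

    def test_median_definition(self):
        draws = [
            ParameterState([1.0], [[v, 0.0]], [1.0], [0.0]) for v in (1.0, 2.0, 30.0)
        ]
        chain = PosteriorChain(draws, np.zeros(3), ModelSpec(K=1), MCMCConfig(seed=0))
        assert posterior_median(chain).centers[0, 0] == 2.0

    def test_matches_sort_oracle(self, rng):
        draws = [
            ParameterState(
                rng.dirichlet([1, 1]), rng.normal(size=(2, 3)),
                rng.uniform(0.5, 2, 2), rng.normal(size=2),
            )
            for _ in range(11)
        ]
        chain = PosteriorChain(draws, np.zeros(11), ModelSpec(K=2), MCMCConfig(seed=0))
        med = posterior_median(chain)
        stacked = np.stack([d.centers for d in draws])
        for k in range(2):
            for t in range(3):
                expected = np.sort(stacked[:, k, t])[5]  # odd count: middle order stat
                assert med.centers[k, t] == expected

    def test_empty_chain_rejected(self):
        chain = PosteriorChain([], np.empty(0), ModelSpec(K=1), MCMCConfig(seed=0))
        with pytest.raises(ValueError):
            posterior_median(chain)


class TestDiagnostics:
    def _chain_from_array(self, arr, chain_ids):
        draws = [
            ParameterState([1.0], [[v, v]], [1.0], [0.0]) for v in arr
        ]
        return PosteriorChain(
            draws, np.zeros(len(arr)), ModelSpec(K=1), MCMCConfig(seed=0),
            chain_index=np.asarray(chain_ids),
        )

    def test_iid_draws_rhat_near_one(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal(4000)
        chain = self._chain_from_array(arr, np.repeat([0, 1], 2000))
        diag = chain_diagnostics(chain)
        assert 0.99 <= diag["z[1,1]"][1] <= 1.01

    def test_disjoint_constant_chains_diverge(self):
        arr = np.concatenate([np.zeros(200), np.ones(200)])
        chain = self._chain_from_array(arr, np.repeat([0, 1], 200))
        diag = chain_diagnostics(chain)
        assert diag["z[1,1]"][1] > 2

    def test_constant_chain_flagged_degenerate(self):
        chain = self._chain_from_array(np.zeros(300), np.zeros(300, dtype=int))
        diag = chain_diagnostics(chain)
        assert diag["z[1,1]"][0] == 0.0  # degenerate ESS flag

    def test_short_single_chain_warns(self):
        chain = self._chain_from_array(np.arange(20.0), np.zeros(20, dtype=int))
        with pytest.warns(RuntimeWarning):
            chain_diagnostics(chain)


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        X = TimeSeriesMatrix(rng.normal(size=(6, 3)))
        spec = ModelSpec.for_data(X, K=2)
        chain = sample_posterior(X, spec, MCMCConfig(n_warmup=20, n_samples=30, seed=1))
        chain.diagnostics = {"z[1,1]": (100.0, 1.01)}
        path = tmp_path / "chain.csv"
        chain_to_csv(chain, path)
        back = chain_from_csv(path)
        np.testing.assert_allclose(
            back.log_posterior_values, chain.log_posterior_values
        )
        np.testing.assert_allclose(back.stacked("centers"), chain.stacked("centers"))
        np.testing.assert_allclose(back.stacked("weights"), chain.stacked("weights"))
        assert back.model.K == 2
        assert back.config.seed == 1
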