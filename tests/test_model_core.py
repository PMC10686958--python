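"""Unit and property tests for the densities and the marginalised posterior."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from rwmix import (
    EmissionFamily,
    ModelSpec,
    ParameterState,
    TimeSeriesMatrix,
    ar1_log_prior,
    component_log_terms,
    emission_log_likelihood,
    log_posterior,
    log_sum_exp,
    random_walk_log_prior,
)
from rwmix.model_core import _emission_logpdf_terms, log_likelihood, log_prior

from conftest import random_instance

FAMILIES = [
    EmissionFamily("gaussian"),
    EmissionFamily("cauchy"),
    EmissionFamily("laplace"),
    EmissionFamily("student_t", df=4.0),
]


class TestLogSumExp:
    def test_single_term_identity(self):
        assert log_sum_exp([3.25]) == pytest.approx(3.25, abs=1e-15)

    def test_two_equal_terms(self):
        assert log_sum_exp([0.0, 0.0]) == pytest.approx(math.log(2.0), abs=1e-14)

    def test_extreme_negative_matches_extended_precision(self):
        # direct summation in 50-digit decimal arithmetic as the oracle
        getcontext().prec = 50
        vals = [-1000.0, -1001.0]
        expected = float(sum(Decimal(v).exp() for v in vals).ln())
        assert log_sum_exp(vals) == pytest.approx(expected, rel=1e-12)

    def test_all_minus_inf(self):
        assert log_sum_exp([-np.inf, -np.inf]) == -np.inf

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            log_sum_exp([])

    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_scipy_logsumexp(self, vals):
        from scipy.special import logsumexp

        assert log_sum_exp(vals) == pytest.approx(float(logsumexp(vals)), rel=1e-12)


class TestRandomWalkPrior:
    def test_zero_increments_unit_variance(self):
        expected = 2 * (-0.5 * math.log(2 * math.pi))
        assert random_walk_log_prior([0.0, 0.0], 0.0, 1.0) == pytest.approx(expected)

    @pytest.mark.parametrize("eps2", [0.1, 1.0, 3.7])
    def test_constant_walk_closed_form(self, eps2):
        d = 5
        got = random_walk_log_prior([1.3] * d, 1.3, eps2)
        assert got == pytest.approx(-(d / 2) * math.log(2 * math.pi * eps2), abs=1e-12)

    def test_matches_per_term_normal_oracle(self, rng):
        z = rng.normal(size=6)
        z0, eps2 = 0.4, 0.9
        prev = np.concatenate([[z0], z[:-1]])
        expected = stats.norm.logpdf(z, prev, math.sqrt(eps2)).sum()
        assert random_walk_log_prior(z, z0, eps2) == pytest.approx(expected, rel=1e-12)

    def test_z0_prior_term_added(self, rng):
        z = rng.normal(size=4)
        base = random_walk_log_prior(z, 0.7, 1.1)
        with_prior = random_walk_log_prior(
            z, 0.7, 1.1, include_z0_prior=True, z0_prior=(0.0, 2.0)
        )
        assert with_prior - base == pytest.approx(
            stats.norm.logpdf(0.7, 0.0, math.sqrt(2.0)), rel=1e-12
        )

    def test_nonpositive_eps2_rejected(self):
        with pytest.raises(ValueError):
            random_walk_log_prior([0.0], 0.0, 0.0)


class TestAR1Prior:
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        st.floats(-2, 2),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rho_one_zero_equals_random_walk(self, z, z0, eps2):
        assert ar1_log_prior(z, z0, 1.0, 0.0, eps2) == pytest.approx(
            random_walk_log_prior(z, z0, eps2), abs=1e-14
        )

    def test_deterministic_recursion_hits_mode(self):
        rho1, rho2, z0, eps2, d = 0.8, 0.5, 1.0, 0.6, 6
        z = []
        prev = z0
        for _ in range(d):
            prev = rho1 * prev + rho2
            z.append(prev)
        expected = -(d / 2) * math.log(2 * math.pi * eps2)
        assert ar1_log_prior(z, z0, rho1, rho2, eps2) == pytest.approx(expected)

    def test_matches_per_term_oracle(self, rng):
        z = rng.normal(size=5)
        z0, rho1, rho2, eps2 = 0.3, 0.9, -0.2, 1.4
        prev = np.concatenate([[z0], z[:-1]])
        expected = stats.norm.logpdf(z, rho1 * prev + rho2, math.sqrt(eps2)).sum()
        assert ar1_log_prior(z, z0, rho1, rho2, eps2) == pytest.approx(
            expected, rel=1e-12
        )


class TestEmission:
    def test_gaussian_at_center(self):
        em = EmissionFamily("gaussian")
        got = emission_log_likelihood([1.0] * 4, [1.0] * 4, 1.0, em)
        assert got == pytest.approx(4 * (-0.5 * math.log(2 * math.pi)))

    def test_cauchy_mode_density(self):
        X = TimeSeriesMatrix(np.zeros((1, 2)))
        terms = _emission_logpdf_terms(np.zeros(1), 1.0, EmissionFamily("cauchy"))
        assert terms[0] == pytest.approx(-math.log(math.pi))
        assert X.d == 2  # matrix type enforces >= 2 time points

    @pytest.mark.parametrize("em", FAMILIES, ids=lambda e: e.family)
    def test_matches_scipy_per_point_oracle(self, em, rng):
        x = rng.normal(size=7)
        c = rng.normal(size=7)
        sigma2 = 1.7
        scale = math.sqrt(sigma2)
        dist = {
            "gaussian": lambda: stats.norm.logpdf(x, c, scale),
            "cauchy": lambda: stats.cauchy.logpdf(x, c, scale),
            "laplace": lambda: stats.laplace.logpdf(x, c, scale),
            "student_t": lambda: stats.t.logpdf(x, em.df, c, scale),
        }[em.family]()
        assert emission_log_likelihood(x, c, sigma2, em) == pytest.approx(
            dist.sum(), rel=1e-12
        )

    @pytest.mark.parametrize("em", FAMILIES, ids=lambda e: e.family)
    def test_density_integrates_to_one(self, em):
        val, _ = quad(
            lambda u: math.exp(float(_emission_logpdf_terms(np.array([u]), 1.3, em)[0])),
            -np.inf,
            np.inf,
            limit=400,
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            emission_log_likelihood([0.0, 1.0], [0.0], 1.0, EmissionFamily())


class TestComponentLogTerms:
    def test_single_component_equals_emission(self, rng):
        X, state, spec = random_instance(rng, K=1)
        terms = component_log_terms(X, state, spec)
        for i in range(X.n):
            expected = emission_log_likelihood(
                X.values[i], state.centers[0], float(state.sigma2[0]), spec.emission
            )
            assert terms[i, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_weight_gives_minus_inf_column(self, rng):
        X, state, spec = random_instance(rng, K=3)
        w = state.weights.copy()
        w[1] = 0.0
        w /= w.sum()
        state = ParameterState(w, state.centers, state.sigma2, state.z0)
        terms = component_log_terms(X, state, spec)
        assert np.all(terms[:, 1] == -np.inf)
        assert np.all(np.isfinite(terms[:, [0, 2]]))

    def test_matches_elementwise_oracle(self, rng):
        X, state, spec = random_instance(rng, n=5, d=4, K=3)
        terms = component_log_terms(X, state, spec)
        for i in range(5):
            for k in range(3):
                expected = math.log(state.weights[k]) + stats.norm.logpdf(
                    X.values[i], state.centers[k], math.sqrt(state.sigma2[k])
                ).sum()
                assert terms[i, k] == pytest.approx(expected, rel=1e-12)


def _naive_log_posterior(X, state, spec):
    """Brute-force oracle: mixture densities in plain (non-log) arithmetic."""
    scale = np.sqrt(state.sigma2)
    dens = {
        "gaussian": stats.norm,
        "cauchy": stats.cauchy,
        "laplace": stats.laplace,
    }
    K = state.K
    per_comp = np.empty((X.n, K))
    for k in range(K):
        if spec.emission.family == "student_t":
            pdf = stats.t.pdf(X.values, spec.emission.df, state.centers[k], scale[k])
        else:
            pdf = dens[spec.emission.family].pdf(X.values, state.centers[k], scale[k])
        per_comp[:, k] = pdf.prod(axis=1)
    if spec.likelihood_form == "per_observation":
        lik = float(np.sum(np.log((state.weights * per_comp).sum(axis=1))))
    else:
        lik = float(np.log(np.sum(state.weights**X.n * per_comp.prod(axis=0))))
    return lik + log_prior(state, spec)


class TestLogPosterior:
    def test_k1_forms_agree(self, rng):
        X, state, spec = random_instance(rng, K=1)
        spec_ds = ModelSpec(
            K=1,
            emission=spec.emission,
            mean_process=spec.mean_process,
            hyperpriors=spec.hyperpriors,
            likelihood_form="dataset_level",
        )
        assert log_posterior(X, state, spec) == pytest.approx(
            log_posterior(X, state, spec_ds), rel=1e-12
        )

    @pytest.mark.parametrize("form", ["per_observation", "dataset_level"])
    @pytest.mark.parametrize("family", ["gaussian", "cauchy", "laplace", "student_t"])
    def test_matches_naive_oracle(self, form, family, rng):
        for _ in range(10):
            n, d, K = rng.integers(1, 7), rng.integers(2, 6), rng.integers(1, 4)
            X, state, spec = random_instance(
                rng, n=int(n), d=int(d), K=int(K), family=family, likelihood_form=form
            )
            assert log_posterior(X, state, spec) == pytest.approx(
                _naive_log_posterior(X, state, spec), rel=1e-10, abs=1e-10
            )

    def test_label_permutation_invariance(self, rng):
        X, state, spec = random_instance(rng, K=3)
        perm = [2, 0, 1]
        spec_p = ModelSpec(
            K=3,
            emission=spec.emission,
            mean_process=spec.mean_process.__class__(
                kind=spec.mean_process.kind,
                eps2=tuple(spec.mean_process.eps2[p] for p in perm),
                z0_prior_mean=spec.mean_process.z0_prior_mean,
                z0_prior_var=spec.mean_process.z0_prior_var,
            ),
            hyperpriors=spec.hyperpriors,
        )
        assert log_posterior(X, state.permuted(perm), spec_p) == pytest.approx(
            log_posterior(X, state, spec), abs=1e-10
        )

    def test_nonfinite_state_rejected(self, rng):
        X, state, spec = random_instance(rng, K=2)
        bad = ParameterState(
            state.weights,
            np.where(np.arange(state.d) == 0, np.nan, state.centers[0])[None, :].repeat(2, 0),
            state.sigma2,
            state.z0,
        )
        with pytest.raises(ValueError):
            log_posterior(X, bad, spec)


class TestTimeSeriesMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TimeSeriesMatrix(np.array([[1.0, np.nan]]))
        with pytest.raises(ValueError):
            TimeSeriesMatrix(np.ones((2, 1)))
        with pytest.raises(ValueError):
            TimeSeriesMatrix(np.ones((2, 3)), series_ids=["a", "a"])
        with pytest.raises(ValueError):
            TimeSeriesMatrix(np.ones((1, 3)), time_labels=[3.0, 2.0, 1.0])
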