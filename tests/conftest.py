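"""Shared fixtures: small random model instances and datasets."""

import numpy as np
import pytest

from rwmix import (
    EmissionFamily,
    HyperPriors,
    MeanProcessSpec,
    ModelSpec,
    ParameterState,
    TimeSeriesMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_instance(rng, n=5, d=4, K=3, family="gaussian", likelihood_form="per_observation"):
    """A consistent random (X, state, spec) triple at moderate magnitudes."""
    X = TimeSeriesMatrix(rng.normal(0.0, 1.0, size=(n, d)))
    w = rng.dirichlet(np.ones(K))
    state = ParameterState(
        weights=w,
        centers=rng.normal(0.0, 1.0, size=(K, d)),
        sigma2=rng.uniform(0.5, 2.0, size=K),
        z0=rng.normal(0.0, 1.0, size=K),
    )
    df = 5.0 if family == "student_t" else None
    spec = ModelSpec(
        K=K,
        emission=EmissionFamily(family, df),
        mean_process=MeanProcessSpec(eps2=tuple(rng.uniform(0.2, 1.5, size=K))),
        hyperpriors=HyperPriors(),
        likelihood_form=likelihood_form,
    )
    return X, state, spec


@pytest.fixture
def flat_clusters():
    """Three well-separated flat clusters at levels -5 / 0 / +5."""
    rng = np.random.default_rng(11)
    levels = np.repeat([-5.0, 0.0, 5.0], 20)
    values = levels[:, None] + rng.normal(0.0, 0.3, size=(60, 8))
    return TimeSeriesMatrix(values), np.repeat([1, 2, 3], 20)
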