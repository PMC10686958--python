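"""Synthetic time-series generators and evaluation metrics.

Three generators cover the benchmark designs used to validate the method:

* ``simulate_mixed_effects`` — series scatter around cluster-specific cubic
  polynomial trends with a per-series random intercept (a gene effect) and
  i.i.d. measurement noise; defaults emulate a 91-series, 3-cluster toy set.
* ``simulate_function_suite`` — 100 series drawn from a fixed registry of
  linear and nonlinear template curves forming clusters of unequal size,
  for K = 1..5.
* ``simulate_doubly_stochastic`` — exact draws from the model's own
  generative process: latent random-walk centres, categorical component
  labels, emission noise around the realised centre.

The metrics resolve label switching explicitly: estimated centres and labels
are only identified up to a permutation of components, so both the centre
MSE and the clustering accuracy are minimised/maximised over permutations.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import expit

from .model_core import EmissionFamily, ModelSpec, TimeSeriesMatrix

__all__ = [
    "SyntheticDataset",
    "simulate_mixed_effects",
    "simulate_function_suite",
    "simulate_doubly_stochastic",
    "permutation_matched_mse",
    "clustering_accuracy",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset together with its ground truth."""

    data: TimeSeriesMatrix
    true_labels: np.ndarray  # n ints in 1..K
    true_centers: np.ndarray  # K x d
    generator_params: dict
    seed: int


# default three-cluster cubic design: 91 series in clusters of 31/30/30
_DEFAULT_CUBICS = (
    (2.0, 1.5, -0.4, 0.02),
    (-1.0, -0.8, 0.25, -0.015),
    (0.5, 0.1, 0.0, 0.0),
)


def simulate_mixed_effects(
    K: int = 3,
    n_per_cluster=(31, 30, 30),
    time_labels=None,
    cubic_coeffs=_DEFAULT_CUBICS,
    random_effect_sd: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """Mixed-effects design: x_ij = xi_k(t_j) + beta_i + eps_ij.

    ``xi_k`` is the cluster-specific cubic polynomial c0 + c1 t + c2 t^2 +
    c3 t^3, ``beta_i ~ N(0, random_effect_sd^2)`` is a per-series intercept
    and ``eps_ij ~ N(0, noise_sd^2)`` i.i.d. measurement error.
    """
    coeffs = np.asarray(cubic_coeffs, dtype=float)
    if coeffs.shape != (K, 4):
        raise ValueError("cubic_coeffs must be K x 4")
    n_per_cluster = tuple(int(m) for m in np.atleast_1d(n_per_cluster))
    if len(n_per_cluster) != K or any(m <= 0 for m in n_per_cluster):
        raise ValueError("n_per_cluster must give a positive size per cluster")
    if not (random_effect_sd > 0 and noise_sd > 0):
        raise ValueError("standard deviations must be > 0")
    if time_labels is None:
        time_labels = np.arange(1.0, 11.0)
    t = np.asarray(time_labels, dtype=float)
    centers = np.stack([np.polyval(c[::-1], t) for c in coeffs])

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, m in enumerate(n_per_cluster):
        beta = rng.normal(0.0, random_effect_sd, size=m)
        eps = rng.normal(0.0, noise_sd, size=(m, t.size))
        rows.append(centers[k][None, :] + beta[:, None] + eps)
        labels.extend([k + 1] * m)
    values = np.vstack(rows)
    data = TimeSeriesMatrix(values, time_labels=t)
    params = {
        "design": "mixed_effects",
        "K": K,
        "n_per_cluster": n_per_cluster,
        "cubic_coeffs": coeffs.tolist(),
        "random_effect_sd": random_effect_sd,
        "noise_sd": noise_sd,
    }
    return SyntheticDataset(data, np.asarray(labels), centers, params, seed)


# fixed template registry, in registry order; unequal cluster sizes come from
# a declining (K, K-1, ..., 1) proportion rule with largest-remainder rounding
_TEMPLATES = (
    ("linear_up", lambda u: -2.0 + 4.0 * u),
    ("linear_down", lambda u: 2.0 - 4.0 * u),
    ("sine", lambda u: 2.0 * np.sin(2.0 * math.pi * u)),
    ("logistic", lambda u: 4.0 * expit(10.0 * (u - 0.5)) - 2.0),
    ("constant", lambda u: np.zeros_like(u)),
)


def function_suite_sizes(K: int, n_total: int) -> tuple[int, ...]:
    """Deterministic unequal cluster sizes: proportional to (K, ..., 1)."""
    props = np.arange(K, 0, -1, dtype=float)
    props /= props.sum()
    raw = props * n_total
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    for idx in np.argsort(-remainder)[: n_total - sizes.sum()]:
        sizes[idx] += 1
    return tuple(int(s) for s in sizes)


def simulate_function_suite(
    K: int,
    n_total: int = 100,
    d: int = 15,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticDataset:
    """K clusters of unequal size drawn around fixed linear/nonlinear curves."""
    if not 1 <= K <= len(_TEMPLATES):
        raise ValueError(f"K must be in 1..{len(_TEMPLATES)}")
    if d < 2:
        raise ValueError("need at least two time points")
    if not noise_sd > 0:
        raise ValueError("noise_sd must be > 0")
    u = np.linspace(0.0, 1.0, d)
    centers = np.stack([f(u) for _, f in _TEMPLATES[:K]])
    sizes = function_suite_sizes(K, n_total)

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, K + 1), sizes)
    values = centers[labels - 1] + rng.normal(0.0, noise_sd, size=(n_total, d))
    data = TimeSeriesMatrix(values, time_labels=np.arange(1.0, d + 1.0))
    params = {
        "design": "function_suite",
        "K": K,
        "templates": [name for name, _ in _TEMPLATES[:K]],
        "sizes": sizes,
        "noise_sd": noise_sd,
    }
    return SyntheticDataset(data, labels, centers, params, seed)


def simulate_doubly_stochastic(
    spec: ModelSpec,
    z0,
    eps2,
    sigma2,
    weights,
    n: int,
    d: int,
    seed: int = 0,
) -> SyntheticDataset:
    """Exact draws from the model's own generative process.

    Centres are realised Gaussian random walks started at ``z0`` with
    increment variance ``eps2``; each series picks component k with
    probability ``weights[k]`` and is emitted around the realised centre with
    the spec's emission family at squared scale ``sigma2``.
    """
    K = spec.K
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), (K,))
    eps2 = np.broadcast_to(np.asarray(eps2, dtype=float), (K,))
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (K,))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (K,) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a length-K probability vector")

    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, 1.0, size=(K, d)) * np.sqrt(eps2)[:, None]
    centers = z0[:, None] + np.cumsum(steps, axis=1)
    labels = rng.choice(K, size=n, p=weights) + 1
    noise = _emission_noise(rng, spec.emission, (n, d))
    values = centers[labels - 1] + noise * np.sqrt(sigma2)[labels - 1][:, None]
    data = TimeSeriesMatrix(values, time_labels=np.arange(1.0, d + 1.0))
    params = {
        "design": "doubly_stochastic",
        "K": K,
        "z0": z0.tolist(),
        "eps2": eps2.tolist(),
        "sigma2": sigma2.tolist(),
        "weights": weights.tolist(),
        "emission": spec.emission.family,
    }
    return SyntheticDataset(data, labels, centers, params, seed)


def _emission_noise(rng: np.random.Generator, emission: EmissionFamily, shape):
    fam = emission.family
    if fam == "gaussian":
        return rng.normal(size=shape)
    if fam == "cauchy":
        return rng.standard_cauchy(size=shape)
    if fam == "laplace":
        return rng.laplace(size=shape)
    return rng.standard_t(emission.df, size=shape)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def permutation_matched_mse(estimated, truth) -> tuple[float, tuple[int, ...]]:
    """Smallest mean squared error between centre sets over permutations.

    Returns ``(mse, perm)`` where ``estimated[perm[k]]`` is matched to
    ``truth[k]``.  Exhaustive search for K <= 8, Hungarian assignment above
    (the objective separates over components, so both are exact).
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth must have the same shape")
    K = est.shape[0]
    # cost[k, j] = mean squared error of matching truth row k to estimate j
    cost = ((tru[:, None, :] - est[None, :, :]) ** 2).mean(axis=2)
    if K <= 8:
        best, best_perm = math.inf, None
        for perm in itertools.permutations(range(K)):
            total = cost[np.arange(K), perm].mean()
            if total < best:
                best, best_perm = total, perm
        return float(best), best_perm
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean()), tuple(int(c) for c in cols)


def clustering_accuracy(estimated_labels, true_labels, K: int) -> float:
    """Best-permutation fraction of exactly matching labels.

    Labels are 1..K with 0 meaning unassigned; unassigned always counts as a
    mismatch.  Exhaustive over permutations for K <= 8, Hungarian above.
    """
    est = np.asarray(estimated_labels, dtype=int)
    tru = np.asarray(true_labels, dtype=int)
    if est.shape != tru.shape:
        raise ValueError("label vectors must have the same length")
    n = est.size
    # match[k, j] = number of series with true label k+1 and estimated j+1
    match = np.zeros((K, K))
    for k in range(K):
        for j in range(K):
            match[k, j] = np.sum((tru == k + 1) & (est == j + 1))
    if K <= 8:
        best = 0.0
        for perm in itertools.permutations(range(K)):
            best = max(best, match[np.arange(K), perm].sum())
        return float(best) / n
    rows, cols = linear_sum_assignment(-match)
    return float(match[rows, cols].sum()) / n


def write_dataset(dataset: SyntheticDataset, csv_path, truth_path=None) -> None:
    """Wide CSV of the series plus a JSON truth sidecar for replay."""
    from .io import write_series_matrix

    csv_path = Path(csv_path)
    write_series_matrix(dataset.data, csv_path)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    payload = {
        "seed": dataset.seed,
        "generator_params": dataset.generator_params,
        "true_labels": dataset.true_labels.tolist(),
        "true_centers": dataset.true_centers.tolist(),
    }
    Path(truth_path).write_text(json.dumps(payload, indent=2))
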