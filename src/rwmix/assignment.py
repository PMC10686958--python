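"""Decoupled assignment of series to estimated component centres.

Assignment happens after (and independently of) the MCMC: given a point
estimate of the model parameters — typically the posterior median — each
series is scored against every component and assigned to the best one.  The
default score converts distance to a probability scale,

    p(x_i in k | theta_k)  propto  (pi_k / sigma_k) exp(-||z_k - x_i||^2 / (2 sigma_k^2)),

normalised over components per series.  Because no membership indicators are
sampled, the same code path classifies held-out or newly arriving series
against a frozen state, thresholding can be re-applied without re-running
any MCMC, and any distance function can replace the probabilistic score.

Unassigned series are encoded with the label 0 (``UNASSIGNED``); assigned
labels are 1..K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .model_core import ParameterState, TimeSeriesMatrix

__all__ = [
    "UNASSIGNED",
    "MembershipMatrix",
    "AssignmentResult",
    "membership_probabilities",
    "assign_hard",
    "assign_by_distance",
    "realized_weights",
    "rethreshold",
    "write_assignment",
    "DISTANCES",
]

UNASSIGNED = 0


@dataclass(frozen=True)
class MembershipMatrix:
    """n x K membership probabilities; every row sums to one."""

    probabilities: np.ndarray
    series_ids: tuple[str, ...]

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2:
            raise ValueError("probabilities must be 2-D")
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "series_ids", tuple(self.series_ids))

    @property
    def n(self) -> int:
        return self.probabilities.shape[0]

    @property
    def K(self) -> int:
        return self.probabilities.shape[1]


@dataclass(frozen=True)
class AssignmentResult:
    """Hard labels plus the memberships and threshold that produced them."""

    labels: np.ndarray  # n ints, 1..K or UNASSIGNED (0)
    memberships: MembershipMatrix | None
    threshold: object  # scalar or per-cluster vector
    realized_weights: np.ndarray

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.labels != UNASSIGNED))


def membership_probabilities(
    X: TimeSeriesMatrix, state: ParameterState, full_gaussian: bool = False
) -> MembershipMatrix:
    """Probability-scale memberships of every series in every component.

    The prefactor is pi_k / sigma_k (sigma to the first power); setting
    ``full_gaussian=True`` switches to the complete Gaussian density's
    sigma_k^d prefactor for sensitivity checks.  Scores are computed in log
    space and normalised per row, so the result is invariant to any common
    rescaling of the unnormalised scores.
    """
    if state.d != X.d:
        raise ValueError("state dimensions do not match the data")
    if np.any(state.sigma2 <= 0):
        raise ValueError("all sigma_k must be strictly positive")
    sigma = np.sqrt(state.sigma2)
    sq = ((X.values[:, None, :] - state.centers[None, :, :]) ** 2).sum(axis=2)
    power = X.d if full_gaussian else 1
    with np.errstate(divide="ignore"):
        log_scores = (
            np.log(state.weights)[None, :]
            - power * np.log(sigma)[None, :]
            - sq / (2.0 * state.sigma2)[None, :]
        )
    m = log_scores.max(axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    p = np.exp(log_scores - m)
    p /= p.sum(axis=1, keepdims=True)
    return MembershipMatrix(probabilities=p, series_ids=X.series_ids)


def _check_threshold(threshold, K) -> np.ndarray:
    """Scalar (global) or length-K (per-cluster) threshold, validated."""
    t = np.asarray(threshold, dtype=float)
    if t.ndim == 0:
        t = np.full(K, float(t))
    elif t.shape != (K,):
        raise ValueError("threshold must be a scalar or one value per cluster")
    if np.any(t < 0) or np.any(t >= 1):
        raise ValueError("threshold must lie in [0, 1)")
    return t


def _result_from_memberships(memberships: MembershipMatrix, threshold) -> AssignmentResult:
    p = memberships.probabilities
    t = _check_threshold(threshold, memberships.K)
    best = p.argmax(axis=1)  # argmax ties -> smallest index (numpy contract)
    best_p = p[np.arange(p.shape[0]), best]
    labels = np.where(best_p >= t[best], best + 1, UNASSIGNED)
    return AssignmentResult(
        labels=labels,
        memberships=memberships,
        threshold=threshold,
        realized_weights=realized_weights(labels, memberships.K),
    )


def assign_hard(memberships: MembershipMatrix, threshold=0.0) -> AssignmentResult:
    """Label every series by its top membership, withholding weak ones.

    A series is assigned to argmax_k p_ik when that maximum reaches the
    threshold, otherwise left unassigned; ties go to the smallest component
    index.  ``threshold`` is a global scalar or a length-K vector of
    per-cluster cutoffs (applied to the winning component's probability).
    """
    return _result_from_memberships(memberships, threshold)


def _euclidean(x, c):
    return float(np.sqrt(((x - c) ** 2).sum()))


def _manhattan(x, c):
    return float(np.abs(x - c).sum())


def _correlation(x, c):
    xc = x - x.mean()
    cc = c - c.mean()
    denom = np.sqrt((xc**2).sum() * (cc**2).sum())
    if denom == 0:
        return 1.0
    return float(1.0 - (xc * cc).sum() / denom)


DISTANCES: dict[str, Callable] = {
    "euclidean": _euclidean,
    "manhattan": _manhattan,
    "correlation": _correlation,
}


def assign_by_distance(
    X: TimeSeriesMatrix,
    centers: np.ndarray,
    distance="probabilistic",
    state: ParameterState | None = None,
) -> AssignmentResult:
    """Nearest-centre assignment under a pluggable distance.

    ``distance`` is a registry name (``euclidean``, ``manhattan``,
    ``correlation`` = 1 - Pearson r, or the default probabilistic score
    ``probabilistic`` which needs the full parameter ``state``) or any callable
    ``f(series, centre) -> float``.  With the probabilistic score the labels
    equal ``assign_hard(membership_probabilities(X, state), 0)`` exactly.
    """
    if distance == "probabilistic":
        if state is None:
            raise ValueError("the probabilistic score requires the full state")
        return assign_hard(membership_probabilities(X, state), 0.0)
    if callable(distance):
        fn = distance
    else:
        try:
            fn = DISTANCES[distance]
        except KeyError:
            raise ValueError(
                f"unknown distance {distance!r}; registry: "
                f"{sorted(DISTANCES) + ['probabilistic']}"
            ) from None
    centers = np.asarray(centers, dtype=float)
    K = centers.shape[0]
    dist = np.array(
        [[fn(x, centers[k]) for k in range(K)] for x in X.values]
    )
    labels = dist.argmin(axis=1) + 1  # argmin ties -> smallest index
    return AssignmentResult(
        labels=labels,
        memberships=None,
        threshold=0.0,
        realized_weights=realized_weights(labels, K),
    )


def realized_weights(labels, K: int) -> np.ndarray:
    """Empirical cluster-size fractions among assigned series.

    A secondary estimate of the mixture weights for cross-validation against
    the sampled pi; the zero vector when nothing is assigned.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels[labels != UNASSIGNED], minlength=K + 1)[1 : K + 1]
    total = counts.sum()
    if total == 0:
        return np.zeros(K)
    return counts / total


def rethreshold(result: AssignmentResult, new_threshold) -> AssignmentResult:
    """Re-cut the stored memberships at a new threshold — no MCMC re-run."""
    if result.memberships is None:
        raise ValueError("result does not retain memberships; re-assign instead")
    return _result_from_memberships(result.memberships, new_threshold)


def write_assignment(result: AssignmentResult, csv_path, sidecar_path=None) -> None:
    """CSV of labels and memberships plus a JSON sidecar of settings."""
    import pandas as pd

    csv_path = Path(csv_path)
    if result.memberships is not None:
        mm = result.memberships
        df = pd.DataFrame(
            mm.probabilities, columns=[f"p_{k + 1}" for k in range(mm.K)]
        )
        df.insert(0, "series_id", mm.series_ids)
        df.insert(
            1,
            "label",
            ["" if l == UNASSIGNED else str(l) for l in result.labels],
        )
        df.insert(2, "max_probability", mm.probabilities.max(axis=1))
    else:
        df = pd.DataFrame(
            {
                "series_id": [f"s{i}" for i in range(result.labels.size)],
                "label": [
                    "" if l == UNASSIGNED else str(l) for l in result.labels
                ],
            }
        )
    df.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    payload = {
        "threshold": result.threshold,
        "realized_weights": result.realized_weights.tolist(),
        "n_assigned": result.n_assigned,
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=2))
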