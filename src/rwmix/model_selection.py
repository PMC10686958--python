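"""Model posterior over candidate models from precomputed per-model chains.

Rather than trans-dimensional jumps, each candidate model (typically the
same structure with K = 1, 2, ..., J components) is fitted independently to
convergence, its marginal likelihood (evidence) is estimated from the chain,
and Bayes' theorem turns evidences plus a model prior into a model
posterior.  Because unused components are not pruned during sampling, models
with extra components can retain support; the *rectified* model posterior
re-aggregates the raw posterior by the number of components that are
actually nonempty after the assignment step, transferring the support of
models with false components to the matching nonempty count.

The evidence estimator is iterative bridge sampling with a moment-matched
Gaussian proposal in unconstrained parameter space (log for sigma^2,
additive log-ratio for the weights); a plain importance-sampling estimator
from the same proposal is kept as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import multivariate_normal

from .assignment import UNASSIGNED, AssignmentResult
from .model_core import (
    ModelSpec,
    ParameterState,
    TimeSeriesMatrix,
    log_likelihood,
    log_posterior,
    log_sum_exp,
)
from .sampler import PosteriorChain

__all__ = [
    "CandidateSet",
    "ModelPosterior",
    "LogEvidence",
    "estimate_log_evidence",
    "model_posterior",
    "effective_component_count",
    "rectify",
    "suggest_k_range",
]


@dataclass(frozen=True)
class CandidateSet:
    """Ordered candidate models with a prior over them (uniform by default).

    A parsimony-favouring geometric prior (ratio < 1 over increasing K) can
    be requested instead of the uniform default.
    """

    models: tuple
    model_prior: np.ndarray | None = None

    def __post_init__(self):
        models = tuple(self.models)
        if not models:
            raise ValueError("candidate set must be non-empty")
        if self.model_prior is None:
            prior = np.full(len(models), 1.0 / len(models))
        else:
            prior = np.asarray(self.model_prior, dtype=float)
            if prior.shape != (len(models),) or abs(prior.sum() - 1.0) > 1e-9:
                raise ValueError("model_prior must be a probability vector")
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "model_prior", prior)

    @classmethod
    def nested_by_k(cls, base: ModelSpec, k_values, geometric_ratio=None):
        """Same structure, increasing K; optionally a geometric prior on K."""
        models = tuple(replace(base, K=int(k)) for k in k_values)
        prior = None
        if geometric_ratio is not None:
            raw = np.power(float(geometric_ratio), np.arange(len(models)))
            prior = raw / raw.sum()
        return cls(models=models, model_prior=prior)

    def is_nested(self) -> bool:
        """True when models share structure and differ only by increasing K."""
        ks = [m.K for m in self.models]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            return False
        ref = self.models[0]
        for m in self.models[1:]:
            if m.emission != ref.emission:
                return False
            if m.mean_process.kind != ref.mean_process.kind:
                return False
            if len(set(m.mean_process.eps2)) > 1 or set(m.mean_process.eps2) != set(
                ref.mean_process.eps2
            ):
                return False
            if m.likelihood_form != ref.likelihood_form:
                return False
        return True


@dataclass(frozen=True)
class ModelPosterior:
    """Raw (and optionally rectified) probabilities over candidate models."""

    raw: np.ndarray
    evidences: np.ndarray
    candidates: CandidateSet
    rectified: dict | None = None  # effective count -> probability mass
    effective_components: tuple | None = None

    def __post_init__(self):
        raw = np.asarray(self.raw, dtype=float)
        if abs(raw.sum() - 1.0) > 1e-9:
            raise ValueError("raw model posterior must sum to 1")
        object.__setattr__(self, "raw", raw)
        if self.rectified is not None and abs(sum(self.rectified.values()) - 1.0) > 1e-9:
            raise ValueError("rectified model posterior must sum to 1")

    def selected_index(self) -> int:
        """Most plausible model; ties broken towards the smallest K."""
        best = float(np.max(self.raw))
        tied = [i for i, p in enumerate(self.raw) if p == best]
        return min(tied, key=lambda i: self.candidates.models[i].K)

    def selected_effective_count(self) -> int:
        """Mode of the rectified posterior (smallest count among ties)."""
        if self.rectified is None:
            raise ValueError("rectified posterior not computed")
        best = max(self.rectified.values())
        return min(c for c, p in self.rectified.items() if p == best)

    def is_multimodal(self, window: float = 0.1) -> bool:
        """Flag when a second model sits within ``window`` of the top one."""
        top = np.sort(self.raw)[::-1]
        return bool(top.size > 1 and (top[0] - top[1]) < window)


# ---------------------------------------------------------------------------
# evidence estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogEvidence:
    """A log marginal-likelihood estimate with a Monte-Carlo standard error."""

    value: float
    mc_se: float
    method: str
    n_draws: int

    def __float__(self) -> float:
        return self.value


def _free_layout(spec: ModelSpec, d: int):
    """(name, size) blocks of the unconstrained free-parameter vector."""
    blocks = []
    if spec.fixed_centers is None:
        for k in range(spec.K):
            if spec.fixed_z0 is None:
                blocks.append((f"z0_{k}", 1))
            blocks.append((f"z_{k}", d))
    if spec.fixed_sigma2 is None:
        blocks.append(("log_sigma2", spec.K))
    if spec.fixed_weights is None and spec.K > 1:
        blocks.append(("alr_pi", spec.K - 1))
    return blocks


def _state_to_vector(state: ParameterState, spec: ModelSpec) -> np.ndarray:
    parts = []
    if spec.fixed_centers is None:
        for k in range(spec.K):
            if spec.fixed_z0 is None:
                parts.append([state.z0[k]])
            parts.append(state.centers[k])
    if spec.fixed_sigma2 is None:
        parts.append(np.log(state.sigma2))
    if spec.fixed_weights is None and spec.K > 1:
        parts.append(np.log(state.weights[:-1]) - math.log(state.weights[-1]))
    return np.concatenate(parts) if parts else np.empty(0)


def _vector_to_state(v: np.ndarray, spec: ModelSpec, d: int) -> tuple[ParameterState, float]:
    """Rebuild a state from the unconstrained vector; also return log|Jacobian|."""
    K = spec.K
    pos = 0
    log_jac = 0.0
    if spec.fixed_centers is None:
        centers = np.empty((K, d))
        z0 = np.empty(K)
        for k in range(K):
            if spec.fixed_z0 is None:
                z0[k] = v[pos]
                pos += 1
            else:
                z0[k] = spec.fixed_z0[k]
            centers[k] = v[pos : pos + d]
            pos += d
    else:
        centers = np.asarray(spec.fixed_centers, dtype=float)
        z0 = (
            np.asarray(spec.fixed_z0, dtype=float)
            if spec.fixed_z0 is not None
            else centers[:, 0]
        )
    if spec.fixed_sigma2 is None:
        log_s2 = v[pos : pos + K]
        pos += K
        sigma2 = np.exp(log_s2)
        log_jac += float(log_s2.sum())
    else:
        sigma2 = np.asarray(spec.fixed_sigma2, dtype=float)
    if spec.fixed_weights is None and K > 1:
        y = v[pos : pos + K - 1]
        pos += K - 1
        full = np.concatenate([y, [0.0]])
        full -= full.max()
        e = np.exp(full)
        weights = e / e.sum()
        log_jac += float(np.log(weights).sum())
    elif spec.fixed_weights is not None:
        weights = np.asarray(spec.fixed_weights, dtype=float)
    else:
        weights = np.ones(1)
    state = ParameterState(weights=weights, centers=centers, sigma2=sigma2, z0=z0)
    return state, log_jac


def _log_target(v: np.ndarray, X: TimeSeriesMatrix, spec: ModelSpec) -> float:
    try:
        state, log_jac = _vector_to_state(v, spec, X.d)
    except (ValueError, FloatingPointError):
        return -np.inf
    try:
        return log_posterior(X, state, spec) + log_jac
    except ValueError:
        return -np.inf


def estimate_log_evidence(
    chain: PosteriorChain,
    X: TimeSeriesMatrix,
    spec: ModelSpec,
    method: str = "bridge",
    seed: int | None = None,
    max_draws: int = 1000,
) -> LogEvidence:
    """Estimate log p(X | model) = log of the integral of likelihood x prior.

    ``bridge`` runs the iterative optimal-bridge update between the chain's
    draws and a moment-matched Gaussian proposal in unconstrained space;
    ``naive_is`` is plain importance sampling from that same proposal, kept
    for reference and cross-checks.  The MC standard error is approximated
    by a two-half split of the draws (half-difference), which is crude but
    serviceable at the chain lengths used here.

    A model with no free parameters integrates trivially: the evidence is the
    log likelihood at the fixed parameter point.
    """
    if method not in ("bridge", "naive_is"):
        raise ValueError("method must be 'bridge' or 'naive_is'")
    if not _free_layout(spec, X.d):
        st, _ = _vector_to_state(np.empty(0), spec, X.d)
        return LogEvidence(float(log_likelihood(X, st, spec)), 0.0, "exact", 0)
    if len(chain) < 500:
        raise ValueError("evidence estimation needs at least 500 draws")
    if seed is None:
        seed = chain.config.seed + 10_007
    rng = np.random.default_rng(seed)

    idx = np.linspace(0, len(chain) - 1, min(max_draws, len(chain))).astype(int)
    V1 = np.stack([_state_to_vector(chain.draws[i], spec) for i in idx])
    mean = V1.mean(axis=0)
    cov = np.cov(V1.T) if V1.shape[1] > 1 else np.atleast_2d(np.var(V1, ddof=1))
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(V1.shape[1])
    try:
        proposal = multivariate_normal(mean=mean, cov=cov)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(
            "degenerate proposal covariance; run a longer chain"
        ) from exc

    N1 = V1.shape[0]
    V2 = proposal.rvs(size=N1, random_state=rng).reshape(N1, -1)
    lq1 = np.array([_log_target(v, X, spec) for v in V1])
    lq2 = np.array([_log_target(v, X, spec) for v in V2])
    lg1 = proposal.logpdf(V1)
    lg2 = proposal.logpdf(V2)

    def run(l1, l2):
        if method == "naive_is":
            return log_sum_exp(l2) - math.log(l2.size)
        return _bridge_iterate(l1, l2)

    # l = log q(v) - log g(v); q is the unnormalised posterior in v-space
    l1 = lq1 - lg1
    l2 = lq2 - lg2
    value = run(l1, l2)
    half = N1 // 2
    v_a = run(l1[:half], l2[:half])
    v_b = run(l1[half:], l2[half:])
    mc_se = abs(v_a - v_b) / 2.0
    return LogEvidence(float(value), float(mc_se), method, N1)


def _bridge_iterate(l1: np.ndarray, l2: np.ndarray, tol=1e-10, max_iter=500) -> float:
    """Meng-Wong optimal-bridge fixed point in log space.

    l1: log-ratios at posterior draws, l2: at proposal draws.  The fixed
    point of  r = mean_j[l2 / (s1 l2 + s2 r)] / mean_i[1 / (s1 l1 + s2 r)]
    is iterated entirely with log-sum-exp arithmetic.
    """
    keep = np.isfinite(l2)
    n1, n2 = l1.size, l2.size
    log_s1 = math.log(n1 / (n1 + n2))
    log_s2 = math.log(n2 / (n1 + n2))
    log_r = float(np.median(l2[keep])) if keep.any() else 0.0
    for _ in range(max_iter):
        den2 = np.logaddexp(log_s1 + l2[keep], log_s2 + log_r)
        den1 = np.logaddexp(log_s1 + l1, log_s2 + log_r)
        log_num = log_sum_exp(l2[keep] - den2) - math.log(n2)
        log_den = log_sum_exp(-den1) - math.log(n1)
        new = log_num - log_den
        if abs(new - log_r) < tol:
            return new
        log_r = new
    return log_r


# ---------------------------------------------------------------------------
# model posterior and rectification
# ---------------------------------------------------------------------------


def model_posterior(evidences, candidates: CandidateSet) -> ModelPosterior:
    """Bayes' theorem over the candidate set: raw_j propto evidence_j x prior_j."""
    ev = np.array([float(e) for e in np.atleast_1d(evidences)], dtype=float)
    if ev.shape != (len(candidates.models),):
        raise ValueError("need exactly one evidence per candidate model")
    with np.errstate(divide="ignore"):
        log_unnorm = ev + np.log(candidates.model_prior)
    norm = log_sum_exp(log_unnorm)
    if norm == -np.inf:
        raise ValueError("all evidences are -inf; no model has support")
    raw = np.exp(log_unnorm - norm)
    return ModelPosterior(raw=raw, evidences=ev, candidates=candidates)


def effective_component_count(assignment: AssignmentResult, K: int) -> int:
    """Number of components that received at least one assigned series."""
    labels = np.asarray(assignment.labels, dtype=int)
    if np.any((labels < 0) | (labels > K)):
        raise ValueError("labels must lie in 1..K or be unassigned (0)")
    return int(np.unique(labels[labels != UNASSIGNED]).size)


def rectify(posterior: ModelPosterior, effective_counts) -> ModelPosterior:
    """Re-aggregate the model posterior by nonempty component count.

    Mass of every model is transferred to its effective (nonempty) component
    count, so models carrying false components support the matching smaller
    count instead.  Requires a nested candidate set (same structure,
    increasing K); total mass is conserved exactly.
    """
    counts = tuple(int(c) for c in np.atleast_1d(effective_counts))
    if len(counts) != posterior.raw.size:
        raise ValueError("need one effective count per model")
    if not posterior.candidates.is_nested():
        raise ValueError("rectification requires models nested by K")
    rectified: dict[int, float] = {}
    for c, p in zip(counts, posterior.raw):
        rectified[c] = rectified.get(c, 0.0) + float(p)
    return ModelPosterior(
        raw=posterior.raw,
        evidences=posterior.evidences,
        candidates=posterior.candidates,
        rectified=rectified,
        effective_components=counts,
    )


# ---------------------------------------------------------------------------
# prior K range
# ---------------------------------------------------------------------------


def suggest_k_range(
    X: TimeSeriesMatrix, k_min: int = 2, k_max: int = 8
) -> tuple[int, dict[int, float]]:
    """Advisory K from Ward hierarchical clustering + mean silhouette width.

    For each k in [k_min, k_max] the series are clustered hierarchically
    (Ward linkage, Euclidean distance) and scored by the mean silhouette
    width; returns the argmax and all scores.  Purely advisory — it informs
    the candidate K range, not the model posterior.
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.metrics import silhouette_score

    if X.n < 3:
        raise ValueError("need at least 3 series to score cluster counts")
    if not (2 <= k_min <= k_max <= X.n - 1):
        raise ValueError("require 2 <= k_min <= k_max <= n - 1")
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
            X.values
        )
        scores[k] = float(silhouette_score(X.values, labels, metric="euclidean"))
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores
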