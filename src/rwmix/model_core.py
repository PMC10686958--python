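"""Core probability model for latent random-walk mixture clustering.

The observed data are ``n`` real-valued time series of length ``d``.  Each
series is modelled as an i.i.d. draw (over time points, given the centre)
from one of ``K`` mixture components.  The centre curve of component ``k``
is a latent first-order random walk

    z_{k,t} ~ N(z_{k,t-1}, eps_k^2),   t = 1..d,

acting as a smoothing prior: the increment variance ``eps_k^2`` controls how
wiggly the component trend may be.  Observations are emitted around the
centre with a per-component variance-like scale ``sigma_k^2`` through one of
four symmetric location-scale families (Gaussian, Cauchy, Laplace,
Student-t).  The component labels are marginalised out, so the per-series
likelihood is a ``log-sum-exp`` over components and no discrete membership
variables are ever sampled.

This module houses the domain types and every density evaluation; it is pure
computation consumed by the sampler, model-selection and assignment modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TimeSeriesMatrix",
    "EmissionFamily",
    "MeanProcessSpec",
    "HyperPriors",
    "ModelSpec",
    "ParameterState",
    "log_sum_exp",
    "random_walk_log_prior",
    "ar1_log_prior",
    "emission_log_likelihood",
    "component_log_terms",
    "log_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)

EMISSION_FAMILIES = ("gaussian", "cauchy", "laplace", "student_t")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A complete n x d matrix of real-valued time series.

    Rows are series (genes, profiles, ...), columns are ordered time points.
    No missing or non-finite entries are allowed; the model has no mechanism
    for imputation.
    """

    values: np.ndarray
    series_ids: tuple[str, ...]
    time_labels: np.ndarray

    def __init__(self, values, series_ids=None, time_labels=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array (series x time)")
        n, d = values.shape
        if n < 1 or d < 2:
            raise ValueError(f"need n >= 1 and d >= 2, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite entry at series index {bad[0]}, time index {bad[1]}"
            )
        if series_ids is None:
            series_ids = tuple(f"s{i}" for i in range(n))
        else:
            series_ids = tuple(str(s) for s in series_ids)
        if len(series_ids) != n:
            raise ValueError("series_ids length does not match number of rows")
        if len(set(series_ids)) != n:
            raise ValueError("series_ids must be unique")
        if time_labels is None:
            time_labels = np.arange(1.0, d + 1.0)
        else:
            time_labels = np.asarray(time_labels, dtype=float)
        if time_labels.shape != (d,):
            raise ValueError("time_labels length does not match number of columns")
        if not np.all(np.diff(time_labels) > 0):
            raise ValueError("time_labels must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "series_ids", series_ids)
        object.__setattr__(self, "time_labels", time_labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmissionFamily:
    """Symmetric location-scale family for the observation noise.

    ``sigma_k^2`` is always carried as the squared scale; the non-Gaussian
    families use ``sqrt(sigma_k^2)`` as their scale parameter so a single
    variance-like quantity is shared across families.
    """

    family: str = "gaussian"
    df: float | None = None

    def __post_init__(self):
        if self.family not in EMISSION_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {EMISSION_FAMILIES}"
            )
        if self.family == "student_t":
            if self.df is None or not self.df > 0:
                raise ValueError("student_t requires df > 0")
        elif self.df is not None:
            raise ValueError("df is only meaningful for the student_t family")


@dataclass(frozen=True)
class MeanProcessSpec:
    """Latent mean-process prior of the component centres.

    ``random_walk`` is the AR(1) special case rho1 = 1, rho2 = 0.  The
    smoothing variances ``eps2`` are fixed, data-scale-dependent values (one
    per component); placing a prior on them is deliberately not the default.
    """

    kind: str = "random_walk"
    eps2: tuple[float, ...] = (1.0,)
    z0_prior_mean: float = 0.0
    z0_prior_var: float = 10.0
    rho1: float = 1.0
    rho2: float = 0.0

    def __post_init__(self):
        if self.kind not in ("random_walk", "ar1"):
            raise ValueError("kind must be 'random_walk' or 'ar1'")
        eps2 = tuple(float(e) for e in np.atleast_1d(self.eps2))
        if any(e <= 0 for e in eps2):
            raise ValueError("all smoothing variances eps2 must be > 0")
        object.__setattr__(self, "eps2", eps2)
        if not self.z0_prior_var > 0:
            raise ValueError("z0_prior_var must be > 0")


@dataclass(frozen=True)
class HyperPriors:
    """Priors on the per-component noise scale and the mixing weights.

    ``sigma2_prior`` is either ``("half_cauchy", scale)`` — a half-Cauchy on
    sigma_k, expressed as a density on sigma_k^2 — or
    ``("inv_gamma", shape, rate)`` on sigma_k^2 directly.  Mixing weights get
    a Dirichlet prior, symmetric with concentration 1 by default (uniform on
    the simplex).
    """

    sigma2_prior: tuple = ("half_cauchy", 1.0)
    pi_prior_concentration: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        name = self.sigma2_prior[0]
        params = tuple(float(p) for p in self.sigma2_prior[1:])
        if name == "half_cauchy":
            if len(params) != 1:
                raise ValueError("half_cauchy takes one scale parameter")
        elif name == "inv_gamma":
            if len(params) != 2:
                raise ValueError("inv_gamma takes (shape, rate)")
        else:
            raise ValueError("sigma2_prior must be half_cauchy or inv_gamma")
        if any(p <= 0 for p in params):
            raise ValueError("prior parameters must be strictly positive")
        conc = tuple(float(a) for a in np.atleast_1d(self.pi_prior_concentration))
        if any(a <= 0 for a in conc):
            raise ValueError("Dirichlet concentrations must be strictly positive")
        object.__setattr__(self, "sigma2_prior", (name, *params))
        object.__setattr__(self, "pi_prior_concentration", conc)

    def sigma2_log_density(self, sigma2: np.ndarray) -> np.ndarray:
        """Elementwise log prior density of sigma^2 values."""
        s2 = np.asarray(sigma2, dtype=float)
        name, *params = self.sigma2_prior
        if name == "half_cauchy":
            (scale,) = params
            sigma = np.sqrt(s2)
            # half-Cauchy on sigma, change of variables d(sigma)/d(sigma2)
            log_hc = math.log(2.0 / math.pi) - math.log(scale) - np.log1p(
                (sigma / scale) ** 2
            )
            return log_hc - np.log(2.0 * sigma)
        (a, b) = params
        return a * math.log(b) - gammaln(a) - (a + 1.0) * np.log(s2) - b / s2


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: K components plus all structural choices.

    ``likelihood_form`` selects between the standard per-series marginalised
    mixture likelihood (``per_observation``, the default) and the
    dataset-level variant where the log-sum-exp is taken over the column sums
    (``dataset_level``); both are exposed because per-series assignment is
    only coherent under the former.

    ``fixed_*`` entries pin a parameter block to a constant (point-mass
    prior).  They exist so restricted models — used for conjugate checks and
    prior-only sampling — share one code path with the full model.
    """

    K: int
    emission: EmissionFamily = field(default_factory=EmissionFamily)
    mean_process: MeanProcessSpec = field(default_factory=MeanProcessSpec)
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    likelihood_form: str = "per_observation"
    fixed_weights: tuple[float, ...] | None = None
    fixed_sigma2: tuple[float, ...] | None = None
    fixed_centers: tuple | None = None
    fixed_z0: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.likelihood_form not in ("per_observation", "dataset_level"):
            raise ValueError(
                "likelihood_form must be 'per_observation' or 'dataset_level'"
            )
        # broadcast a shared smoothing variance to all K components
        eps2 = self.mean_process.eps2
        if len(eps2) == 1 and self.K > 1:
            object.__setattr__(
                self, "mean_process", replace(self.mean_process, eps2=eps2 * self.K)
            )
        elif len(eps2) != self.K:
            raise ValueError("eps2 must have length 1 or K")
        conc = self.hyperpriors.pi_prior_concentration
        if len(conc) == 1 and self.K > 1:
            object.__setattr__(
                self,
                "hyperpriors",
                replace(self.hyperpriors, pi_prior_concentration=conc * self.K),
            )
        elif len(conc) != self.K:
            raise ValueError("pi_prior_concentration must have length 1 or K")
        for name in ("fixed_weights", "fixed_sigma2", "fixed_z0"):
            val = getattr(self, name)
            if val is not None:
                val = tuple(float(v) for v in np.atleast_1d(val))
                if len(val) != self.K:
                    raise ValueError(f"{name} must have length K")
                object.__setattr__(self, name, val)
        if self.fixed_centers is not None:
            fc = np.asarray(self.fixed_centers, dtype=float)
            if fc.ndim != 2 or fc.shape[0] != self.K:
                raise ValueError("fixed_centers must be a K x d array")
            object.__setattr__(
                self, "fixed_centers", tuple(tuple(row) for row in fc)
            )

    @classmethod
    def for_data(
        cls,
        X: TimeSeriesMatrix,
        K: int,
        eps2: float | Sequence[float] = None,
        emission: EmissionFamily | None = None,
        **kwargs,
    ) -> "ModelSpec":
        """Build a spec with data-scale-dependent default priors.

        The half-Cauchy scale for sigma_k is the sample standard deviation of
        X; the z0 prior is Normal(grand mean, 10 x sample variance); the
        default smoothing variance is 0.15 in the units of the data variance,
        scaled by the sample variance.
        """
        gm = float(np.mean(X.values))
        var = float(np.var(X.values))
        sd = math.sqrt(var) if var > 0 else 1.0
        if eps2 is None:
            eps2 = 0.15 * max(var, 1e-12)
        mp = MeanProcessSpec(
            kind=kwargs.pop("kind", "random_walk"),
            eps2=tuple(np.atleast_1d(eps2)),
            z0_prior_mean=gm,
            z0_prior_var=10.0 * max(var, 1e-12),
        )
        hp = HyperPriors(sigma2_prior=("half_cauchy", sd))
        return cls(
            K=K,
            emission=emission or EmissionFamily(),
            mean_process=mp,
            hyperpriors=hp,
            **kwargs,
        )


@dataclass(frozen=True)
class ParameterState:
    """One value of theta = (pi, z, sigma^2, z0 [, rho])."""

    weights: np.ndarray
    centers: np.ndarray
    sigma2: np.ndarray
    z0: np.ndarray
    ar_params: np.ndarray | None = None

    def __init__(self, weights, centers, sigma2, z0, ar_params=None):
        weights = np.asarray(weights, dtype=float)
        centers = np.asarray(centers, dtype=float)
        sigma2 = np.asarray(sigma2, dtype=float)
        z0 = np.asarray(z0, dtype=float)
        K = weights.shape[0]
        if centers.ndim != 2 or centers.shape[0] != K:
            raise ValueError("centers must be K x d")
        if sigma2.shape != (K,) or z0.shape != (K,):
            raise ValueError("sigma2 and z0 must have length K")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(sigma2 <= 0):
            raise ValueError("sigma2 entries must be strictly positive")
        if ar_params is not None:
            ar_params = np.asarray(ar_params, dtype=float)
            if ar_params.shape != (K, 2):
                raise ValueError("ar_params must be K x 2 (rho1, rho2 per component)")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "z0", z0)
        object.__setattr__(self, "ar_params", ar_params)

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def permuted(self, perm: Sequence[int]) -> "ParameterState":
        """Return the state with components reindexed by ``perm``."""
        perm = np.asarray(perm, dtype=int)
        return ParameterState(
            weights=self.weights[perm],
            centers=self.centers[perm],
            sigma2=self.sigma2[perm],
            z0=self.z0[perm],
            ar_params=None if self.ar_params is None else self.ar_params[perm],
        )


# ---------------------------------------------------------------------------
# primitive densities
# ---------------------------------------------------------------------------


def log_sum_exp(values) -> float:
    """Overflow-safe log(sum(exp(values))) via the max-shift identity.

    Returns -inf iff every entry is -inf.  This primitive underlies both the
    marginalised mixture likelihood and model-posterior normalisation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("log_sum_exp of an empty sequence is undefined")
    m = np.max(v)
    if not np.isfinite(m):
        if m == -np.inf:
            return -np.inf
        raise ValueError("log_sum_exp inputs must be finite or -inf")
    return float(m + np.log(np.sum(np.exp(v - m))))


def _normal_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (x - np.asarray(mean)) ** 2 / var


def random_walk_log_prior(
    z,
    z0: float,
    eps2: float,
    include_z0_prior: bool = False,
    z0_prior: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Log density of a Gaussian random-walk centre curve.

    sum_t log N(z_t | z_{t-1}, eps2) with z_0 = ``z0``; optionally adds the
    log density of ``z0`` under its own Normal(mean, var) prior.
    """
    if not eps2 > 0:
        raise ValueError("eps2 must be > 0")
    z = np.asarray(z, dtype=float)
    prev = np.concatenate(([z0], z[:-1]))
    out = float(np.sum(_normal_logpdf(z, prev, eps2)))
    if include_z0_prior:
        mean, var = z0_prior
        if not var > 0:
            raise ValueError("z0 prior variance must be > 0")
        out += float(_normal_logpdf(z0, mean, var))
    return out


def ar1_log_prior(z, z0: float, rho1: float, rho2: float, eps2: float) -> float:
    """Log density of an AR(1)-mean centre curve.

    sum_t log N(z_t | rho1 * z_{t-1} + rho2, eps2); rho1 = 1, rho2 = 0
    recovers the random-walk prior exactly.
    """
    if not eps2 > 0:
        raise ValueError("eps2 must be > 0")
    z = np.asarray(z, dtype=float)
    prev = np.concatenate(([z0], z[:-1]))
    return float(np.sum(_normal_logpdf(z, rho1 * prev + rho2, eps2)))


def _emission_logpdf_terms(resid: np.ndarray, sigma2: float, emission: EmissionFamily):
    """Elementwise log density of residuals under the emission family."""
    scale = math.sqrt(sigma2)
    u = resid / scale
    fam = emission.family
    if fam == "gaussian":
        return -0.5 * u * u - 0.5 * _LOG_2PI - math.log(scale)
    if fam == "cauchy":
        return -math.log(math.pi) - math.log(scale) - np.log1p(u * u)
    if fam == "laplace":
        return -math.log(2.0 * scale) - np.abs(u)
    df = emission.df
    const = (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
    )
    return const - (df + 1.0) / 2.0 * np.log1p(u * u / df)


def emission_log_likelihood(x, center, sigma2: float, emission: EmissionFamily) -> float:
    """Log likelihood of one series given one component centre.

    Time points are treated as independent given the centre curve, so this is
    a sum of per-point log densities with scale sqrt(sigma2).
    """
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    if x.shape != center.shape:
        raise ValueError("series and centre must have the same length")
    if not sigma2 > 0:
        raise ValueError("sigma2 must be > 0")
    return float(np.sum(_emission_logpdf_terms(x - center, sigma2, emission)))


def emission_log_likelihood_matrix(
    values: np.ndarray, state: ParameterState, emission: EmissionFamily
) -> np.ndarray:
    """n x K matrix of per-series per-component emission log likelihoods."""
    n = values.shape[0]
    out = np.empty((n, state.K))
    for k in range(state.K):
        resid = values - state.centers[k]
        out[:, k] = _emission_logpdf_terms(resid, float(state.sigma2[k]), emission).sum(
            axis=1
        )
    return out


def component_log_terms(
    X: TimeSeriesMatrix, state: ParameterState, spec: ModelSpec
) -> np.ndarray:
    """n x K matrix of log pi_k + log f_k(x_i); -inf where pi_k = 0."""
    if state.K != spec.K or state.d != X.d:
        raise ValueError("state dimensions do not match spec and data")
    ll = emission_log_likelihood_matrix(X.values, state, spec.emission)
    with np.errstate(divide="ignore"):
        log_pi = np.log(state.weights)
    return log_pi[None, :] + ll


def _mean_process_log_prior(state: ParameterState, spec: ModelSpec) -> float:
    mp = spec.mean_process
    total = 0.0
    for k in range(state.K):
        if mp.kind == "random_walk":
            total += random_walk_log_prior(
                state.centers[k], float(state.z0[k]), mp.eps2[k]
            )
        else:
            if state.ar_params is not None:
                rho1, rho2 = state.ar_params[k]
            else:
                rho1, rho2 = mp.rho1, mp.rho2
            total += ar1_log_prior(
                state.centers[k], float(state.z0[k]), rho1, rho2, mp.eps2[k]
            )
        if spec.fixed_z0 is None:
            total += float(
                _normal_logpdf(state.z0[k], mp.z0_prior_mean, mp.z0_prior_var)
            )
    return total


def _dirichlet_log_prior(weights: np.ndarray, conc: Sequence[float]) -> float:
    a = np.asarray(conc, dtype=float)
    const = float(gammaln(a.sum()) - gammaln(a).sum())
    terms = np.where(a == 1.0, 0.0, (a - 1.0) * np.log(weights))
    return const + float(np.sum(terms))


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior of all free parameter blocks (fixed blocks contribute 0)."""
    total = 0.0
    if spec.fixed_centers is None:
        total += _mean_process_log_prior(state, spec)
    if spec.fixed_sigma2 is None:
        total += float(np.sum(spec.hyperpriors.sigma2_log_density(state.sigma2)))
    if spec.fixed_weights is None:
        total += _dirichlet_log_prior(
            state.weights, spec.hyperpriors.pi_prior_concentration
        )
    return total


def log_likelihood(
    X: TimeSeriesMatrix, state: ParameterState, spec: ModelSpec
) -> float:
    """Marginalised mixture log likelihood in the form selected by the spec."""
    terms = component_log_terms(X, state, spec)
    if spec.likelihood_form == "per_observation":
        return float(sum(log_sum_exp(row) for row in terms))
    return log_sum_exp(terms.sum(axis=0))


def log_posterior(X: TimeSeriesMatrix, state: ParameterState, spec: ModelSpec) -> float:
    """Unnormalised log posterior: marginalised likelihood plus all priors.

    ``per_observation`` (default) takes a log-sum-exp over components per
    series and sums over series; ``dataset_level`` takes a single log-sum-exp
    over the component-wise column sums.
    """
    for arr in (state.weights, state.centers, state.sigma2, state.z0):
        if not np.all(np.isfinite(arr)):
            raise ValueError("state contains non-finite entries")
    return log_likelihood(X, state, spec) + log_prior(state, spec)
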