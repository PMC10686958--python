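"""Adaptive blockwise Metropolis-within-Gibbs sampling of one candidate model.

One fully converged chain per candidate model is the unit of work: model
comparison downstream consumes these per-model chains, so each model can be
run independently (and in parallel across processes if desired) with budgets
chosen so it is known to converge.

Parameter blocks and proposals:

* centre block, one per component — joint random-walk proposal on
  ``(z0_k, z_k)``;
* noise block, one per component — random-walk proposal on ``log sigma2_k``
  (log-normal proposal, Jacobian included);
* weight block — logistic-normal proposal: a Gaussian step on the additive
  log-ratio transform of ``pi`` with the transform Jacobian included.

Proposal scales adapt towards ~35% acceptance during warmup only, so the
kept draws come from a fixed transition kernel with the posterior invariant.
Mixture posteriors are invariant under permutations of component labels;
``relabel_chain`` resolves this by matching every draw's centres to a running
reference, which never changes any draw's log posterior.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.optimize import linear_sum_assignment

from .model_core import (
    EmissionFamily,
    HyperPriors,
    MeanProcessSpec,
    ModelSpec,
    ParameterState,
    TimeSeriesMatrix,
    _dirichlet_log_prior,
    _normal_logpdf,
    ar1_log_prior,
    emission_log_likelihood_matrix,
    log_posterior,
    log_sum_exp,
    random_walk_log_prior,
)

__all__ = [
    "MCMCConfig",
    "PosteriorChain",
    "InitializationError",
    "initialize_state",
    "sample_posterior",
    "relabel_chain",
    "posterior_median",
    "chain_diagnostics",
    "chain_to_csv",
    "chain_from_csv",
]

_ADAPT_TARGET = 0.35  # middle of the 0.25-0.45 acceptance band


class InitializationError(RuntimeError):
    """Raised when the log posterior is not finite at the initial state."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class MCMCConfig:
    """Iteration budgets, seeding and proposal settings for one model fit.

    ``mode`` presets: ``fast`` = 1 chain, 1000 warmup, 1000 kept draws;
    ``slow`` = 4 chains, 5000 warmup, 5000 kept draws per chain.
    """

    n_chains: int = 1
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    proposal_scales: dict = field(default_factory=dict)
    adapt: bool = True
    mode: str | None = None
    prior_only: bool = False

    def __post_init__(self):
        if self.n_chains < 1 or self.n_samples < 1 or self.n_warmup < 0:
            raise ValueError("chain/iteration budgets must be positive")
        if self.mode is not None and self.mode not in ("fast", "slow"):
            raise ValueError("mode must be 'fast' or 'slow'")

    @classmethod
    def preset(cls, mode: str, seed: int = 0, **overrides) -> "MCMCConfig":
        budgets = {
            "fast": dict(n_chains=1, n_warmup=1000, n_samples=1000),
            "slow": dict(n_chains=4, n_warmup=5000, n_samples=5000),
        }
        if mode not in budgets:
            raise ValueError("mode must be 'fast' or 'slow'")
        kw = {**budgets[mode], "seed": seed, "mode": mode}
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PosteriorChain:
    """Ordered post-warmup draws from one (possibly multi-chain) model fit."""

    draws: list
    log_posterior_values: np.ndarray
    model: ModelSpec
    config: MCMCConfig
    diagnostics: dict = field(default_factory=dict)
    chain_index: np.ndarray | None = None

    def __post_init__(self):
        self.log_posterior_values = np.asarray(self.log_posterior_values, dtype=float)
        if len(self.draws) != self.log_posterior_values.size:
            raise ValueError("draws and log_posterior_values lengths differ")
        if self.chain_index is None:
            self.chain_index = np.zeros(len(self.draws), dtype=int)

    def __len__(self) -> int:
        return len(self.draws)

    def stacked(self, attr: str) -> np.ndarray:
        """Stack one ParameterState attribute across draws (draws first)."""
        return np.stack([getattr(s, attr) for s in self.draws])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_state(X: TimeSeriesMatrix, spec: ModelSpec, seed: int = 0) -> ParameterState:
    """Deterministic spread-out starting state.

    Series are ranked by their overall mean and cut into K quantile slices;
    each initial centre is the column mean of one slice, lightly smoothed by
    a 3-point moving average (K >= 2 only), which avoids empty-component
    starts.  For K = 1 the centre is exactly the column-mean curve.
    """
    K = spec.K
    if K > X.n:
        raise ValueError(f"K = {K} exceeds the number of series n = {X.n}")
    if spec.fixed_centers is not None:
        centers = np.asarray(spec.fixed_centers, dtype=float)
    else:
        order = np.argsort(X.values.mean(axis=1), kind="stable")
        slices = np.array_split(order, K)
        centers = np.stack([X.values[idx].mean(axis=0) for idx in slices])
        if K > 1:
            padded = np.pad(centers, ((0, 0), (1, 1)), mode="edge")
            centers = (padded[:, :-2] + padded[:, 1:-1] + padded[:, 2:]) / 3.0
    if spec.fixed_sigma2 is not None:
        sigma2 = np.asarray(spec.fixed_sigma2, dtype=float)
    else:
        sigma2 = np.full(K, max(float(np.var(X.values)), 1e-8))
    if spec.fixed_weights is not None:
        weights = np.asarray(spec.fixed_weights, dtype=float)
    else:
        weights = np.full(K, 1.0 / K)
    if spec.fixed_z0 is not None:
        z0 = np.asarray(spec.fixed_z0, dtype=float)
    else:
        z0 = centers[:, 0].copy()
    return ParameterState(weights=weights, centers=centers, sigma2=sigma2, z0=z0)


# ---------------------------------------------------------------------------
# posterior evaluation with per-block caching
# ---------------------------------------------------------------------------


class _ModelEval:
    """Caches the n x K emission log-likelihood matrix between block moves."""

    def __init__(self, X: TimeSeriesMatrix, spec: ModelSpec, prior_only: bool):
        self.X = X
        self.spec = spec
        self.prior_only = prior_only

    def emission_col(self, center: np.ndarray, sigma2: float) -> np.ndarray:
        from .model_core import _emission_logpdf_terms

        resid = self.X.values - center
        return _emission_logpdf_terms(resid, sigma2, self.spec.emission).sum(axis=1)

    def loglik_from_matrix(self, E: np.ndarray, weights: np.ndarray) -> float:
        if self.prior_only:
            return 0.0
        with np.errstate(divide="ignore"):
            terms = np.log(weights)[None, :] + E
        if self.spec.likelihood_form == "per_observation":
            m = terms.max(axis=1, keepdims=True)
            m = np.where(np.isfinite(m), m, 0.0)
            return float(
                np.sum(m[:, 0] + np.log(np.exp(terms - m).sum(axis=1)))
            )
        return log_sum_exp(terms.sum(axis=0))

    def center_log_prior(self, k: int, z: np.ndarray, z0: float) -> float:
        mp = self.spec.mean_process
        if mp.kind == "random_walk":
            out = random_walk_log_prior(z, z0, mp.eps2[k])
        else:
            out = ar1_log_prior(z, z0, mp.rho1, mp.rho2, mp.eps2[k])
        if self.spec.fixed_z0 is None:
            out += float(_normal_logpdf(z0, mp.z0_prior_mean, mp.z0_prior_var))
        return out

    def sigma2_log_prior(self, sigma2_k: float) -> float:
        return float(
            self.spec.hyperpriors.sigma2_log_density(np.asarray([sigma2_k]))[0]
        )

    def weights_log_prior(self, weights: np.ndarray) -> float:
        return _dirichlet_log_prior(
            weights, self.spec.hyperpriors.pi_prior_concentration
        )


def _alr(weights: np.ndarray) -> np.ndarray:
    return np.log(weights[:-1]) - math.log(weights[-1])


def _inv_alr(y: np.ndarray) -> np.ndarray:
    full = np.concatenate([y, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def sample_posterior(
    X: TimeSeriesMatrix, spec: ModelSpec, config: MCMCConfig
) -> PosteriorChain:
    """Run the adaptive blockwise sampler and return the post-warmup draws.

    Deterministic given ``config.seed``: chain c uses a Generator seeded with
    ``seed + c``.  The stored log-posterior values are recomputed from
    scratch for every kept draw, which doubles as a guard against cache
    drift in the incremental likelihood updates.
    """
    draws: list[ParameterState] = []
    lps: list[float] = []
    chain_idx: list[int] = []
    for c in range(config.n_chains):
        d_c, l_c = _run_single_chain(X, spec, config, seed=config.seed + c)
        draws.extend(d_c)
        lps.extend(l_c)
        chain_idx.extend([c] * len(d_c))
    chain = PosteriorChain(
        draws=draws,
        log_posterior_values=np.asarray(lps),
        model=spec,
        config=config,
        chain_index=np.asarray(chain_idx),
    )
    return chain


def _run_single_chain(X, spec, config, seed):
    rng = np.random.default_rng(seed)
    ev = _ModelEval(X, spec, config.prior_only)
    state = initialize_state(X, spec, seed)
    K, d = spec.K, X.d

    weights = state.weights.copy()
    centers = state.centers.copy()
    sigma2 = state.sigma2.copy()
    z0 = state.z0.copy()

    if config.prior_only:
        E = np.zeros((X.n, K))
    else:
        E = np.stack(
            [ev.emission_col(centers[k], float(sigma2[k])) for k in range(K)], axis=1
        )
    loglik = ev.loglik_from_matrix(E, weights)
    center_priors = np.array(
        [ev.center_log_prior(k, centers[k], float(z0[k])) for k in range(K)]
    )
    sigma_priors = np.array([ev.sigma2_log_prior(float(s)) for s in sigma2])
    if not np.isfinite(
        loglik + center_priors.sum() + sigma_priors.sum()
    ):
        raise InitializationError(
            "log posterior not finite at the initial state",
            diagnostics={"loglik": loglik, "center_priors": center_priors.tolist()},
        )

    data_sd = float(np.std(X.values)) or 1.0
    scales = {f"z{k}": 0.05 * data_sd for k in range(K)}
    scales.update({f"sigma2_{k}": 0.3 for k in range(K)})
    scales["pi"] = 0.3
    scales.update(config.proposal_scales)

    sample_centers = spec.fixed_centers is None
    sample_sigma2 = spec.fixed_sigma2 is None
    sample_weights = spec.fixed_weights is None and K > 1

    kept_draws, kept_lps = [], []
    total = config.n_warmup + config.n_samples
    for it in range(total):
        in_warmup = it < config.n_warmup
        adapt_rate = min(0.25, 2.0 / math.sqrt(it + 10.0)) if (
            in_warmup and config.adapt
        ) else 0.0

        if sample_centers:
            for k in range(K):
                key = f"z{k}"
                step = rng.standard_normal(d + 1) * scales[key] / math.sqrt(d + 1)
                new_z0k = z0[k] + (step[0] if spec.fixed_z0 is None else 0.0)
                new_zk = centers[k] + step[1:]
                new_prior = ev.center_log_prior(k, new_zk, float(new_z0k))
                new_col = (
                    E[:, k]
                    if config.prior_only
                    else ev.emission_col(new_zk, float(sigma2[k]))
                )
                if config.prior_only:
                    new_loglik = loglik
                else:
                    E_new = E.copy()
                    E_new[:, k] = new_col
                    new_loglik = ev.loglik_from_matrix(E_new, weights)
                log_alpha = (new_loglik - loglik) + (new_prior - center_priors[k])
                accept = math.log(rng.random()) < log_alpha
                if accept:
                    centers[k] = new_zk
                    z0[k] = new_z0k
                    center_priors[k] = new_prior
                    if not config.prior_only:
                        E[:, k] = new_col
                        loglik = new_loglik
                if adapt_rate:
                    scales[key] *= math.exp(adapt_rate * (float(accept) - _ADAPT_TARGET))

        if sample_sigma2:
            for k in range(K):
                key = f"sigma2_{k}"
                new_s2 = float(sigma2[k] * math.exp(scales[key] * rng.standard_normal()))
                new_prior = ev.sigma2_log_prior(new_s2)
                if config.prior_only:
                    new_loglik = loglik
                else:
                    new_col = ev.emission_col(centers[k], new_s2)
                    E_new = E.copy()
                    E_new[:, k] = new_col
                    new_loglik = ev.loglik_from_matrix(E_new, weights)
                # log-scale random walk: Jacobian ratio sigma2'/sigma2
                log_alpha = (
                    (new_loglik - loglik)
                    + (new_prior - sigma_priors[k])
                    + math.log(new_s2 / sigma2[k])
                )
                accept = math.log(rng.random()) < log_alpha
                if accept:
                    sigma2[k] = new_s2
                    sigma_priors[k] = new_prior
                    if not config.prior_only:
                        E[:, k] = new_col
                        loglik = new_loglik
                if adapt_rate:
                    scales[key] *= math.exp(adapt_rate * (float(accept) - _ADAPT_TARGET))

        if sample_weights:
            y = _alr(weights)
            y_new = y + rng.standard_normal(K - 1) * scales["pi"]
            w_new = _inv_alr(y_new)
            if np.all(w_new > 0):
                new_loglik = ev.loglik_from_matrix(E, w_new)
                # inverse-ALR Jacobian determinant is prod_k pi_k
                log_alpha = (
                    (new_loglik - loglik)
                    + (ev.weights_log_prior(w_new) - ev.weights_log_prior(weights))
                    + (np.log(w_new).sum() - np.log(weights).sum())
                )
                accept = math.log(rng.random()) < log_alpha
            else:
                accept = False
            if accept:
                weights = w_new
                loglik = new_loglik
            if adapt_rate:
                scales["pi"] *= math.exp(adapt_rate * (float(accept) - _ADAPT_TARGET))

        if not in_warmup:
            st = ParameterState(
                weights=weights.copy(),
                centers=centers.copy(),
                sigma2=sigma2.copy(),
                z0=z0.copy(),
            )
            kept_draws.append(st)
            if config.prior_only:
                kept_lps.append(
                    center_priors.sum()
                    + sigma_priors.sum()
                    + (ev.weights_log_prior(weights) if sample_weights else 0.0)
                )
            else:
                kept_lps.append(log_posterior(X, st, spec))
    return kept_draws, kept_lps


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def relabel_chain(chain: PosteriorChain) -> PosteriorChain:
    """Undo label switching by matching each draw's centres to a running mean.

    The permutation minimising the summed squared distance between a draw's
    centres and the running mean of previously relabeled centres is found by
    Hungarian assignment (exact).  Log-posterior values are untouched — the
    posterior is symmetric under component permutations.
    """
    if len(chain) == 0:
        raise ValueError("cannot relabel an empty chain")
    K = chain.model.K
    ref = chain.draws[0].centers.astype(float).copy()
    new_draws = []
    count = 0
    for st in chain.draws:
        cost = ((ref[:, None, :] - st.centers[None, :, :]) ** 2).sum(axis=2)
        _, perm = linear_sum_assignment(cost)
        st2 = st.permuted(perm) if not np.array_equal(perm, np.arange(K)) else st
        new_draws.append(st2)
        count += 1
        ref += (st2.centers - ref) / count
    return PosteriorChain(
        draws=new_draws,
        log_posterior_values=chain.log_posterior_values.copy(),
        model=chain.model,
        config=chain.config,
        diagnostics=dict(chain.diagnostics),
        chain_index=chain.chain_index.copy(),
    )


def posterior_median(chain: PosteriorChain) -> ParameterState:
    """Elementwise posterior median of every parameter (weights renormalised)."""
    if len(chain) == 0:
        raise ValueError("cannot take the median of an empty chain")
    weights = np.median(chain.stacked("weights"), axis=0)
    weights = weights / weights.sum()
    return ParameterState(
        weights=weights,
        centers=np.median(chain.stacked("centers"), axis=0),
        sigma2=np.median(chain.stacked("sigma2"), axis=0),
        z0=np.median(chain.stacked("z0"), axis=0),
    )


def _flatten_names(K: int, d: int) -> list[str]:
    names = []
    for k in range(K):
        names.append(f"z0[{k + 1}]")
        for t in range(d):
            names.append(f"z[{k + 1},{t + 1}]")
    names.extend(f"sigma2[{k + 1}]" for k in range(K))
    names.extend(f"pi[{k + 1}]" for k in range(K))
    return names


def _flatten_draw(st: ParameterState) -> np.ndarray:
    parts = []
    for k in range(st.K):
        parts.append([st.z0[k]])
        parts.append(st.centers[k])
    parts.append(st.sigma2)
    parts.append(st.weights)
    return np.concatenate(parts)


def chain_diagnostics(chain: PosteriorChain) -> dict:
    """Split-R-hat and bulk effective sample size per scalar parameter.

    R-hat uses the standard split-chain formula (each chain halved), which
    yields +inf rather than NaN when between-chain variance dominates a zero
    within-chain variance; bulk ESS comes from arviz.  With a single short
    chain (< 100 draws) a warning is emitted and partial output returned.
    """
    n = len(chain)
    n_chains = int(chain.chain_index.max()) + 1
    if n_chains < 2 and n < 100:
        warnings.warn(
            "too few draws for reliable diagnostics; returning partial output",
            RuntimeWarning,
        )
    K, d = chain.model.K, chain.draws[0].d
    names = _flatten_names(K, d)
    flat = np.stack([_flatten_draw(s) for s in chain.draws])  # (draws, P)
    per_chain = [flat[chain.chain_index == c] for c in range(n_chains)]
    min_len = min(len(p) for p in per_chain)
    arr = np.stack([p[:min_len] for p in per_chain])  # (chains, draws, P)

    out = {}
    ess_vals = _bulk_ess(arr)
    for j, name in enumerate(names):
        rhat = _split_rhat(arr[:, :, j])
        out[name] = (float(ess_vals[j]), float(rhat))
    return out


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter, x shaped (chains, draws)."""
    m, n = x.shape
    half = n // 2
    if half < 1:
        return float("nan")
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    within = splits.var(axis=1, ddof=1).mean()
    between = half * splits.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else float("inf")
    var_plus = (half - 1) / half * within + between / half
    return float(math.sqrt(var_plus / within))


def _bulk_ess(arr: np.ndarray) -> np.ndarray:
    """Bulk ESS per parameter via arviz; constant parameters flagged as 0."""
    import arviz as az

    n_par = arr.shape[2]
    out = np.empty(n_par)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(n_par):
            x = arr[:, :, j]
            if np.ptp(x) == 0:
                out[j] = 0.0  # degenerate: constant chain
                continue
            out[j] = float(az.ess(az.convert_to_dataset(x))["x"].values)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "K": spec.K,
        "emission": {"family": spec.emission.family, "df": spec.emission.df},
        "mean_process": dataclasses.asdict(spec.mean_process),
        "hyperpriors": {
            "sigma2_prior": list(spec.hyperpriors.sigma2_prior),
            "pi_prior_concentration": list(spec.hyperpriors.pi_prior_concentration),
        },
        "likelihood_form": spec.likelihood_form,
        "fixed_weights": spec.fixed_weights,
        "fixed_sigma2": spec.fixed_sigma2,
        "fixed_centers": spec.fixed_centers,
        "fixed_z0": spec.fixed_z0,
    }


def _spec_from_dict(payload: dict) -> ModelSpec:
    return ModelSpec(
        K=payload["K"],
        emission=EmissionFamily(**payload["emission"]),
        mean_process=MeanProcessSpec(**payload["mean_process"]),
        hyperpriors=HyperPriors(
            sigma2_prior=tuple(payload["hyperpriors"]["sigma2_prior"]),
            pi_prior_concentration=tuple(
                payload["hyperpriors"]["pi_prior_concentration"]
            ),
        ),
        likelihood_form=payload["likelihood_form"],
        fixed_weights=payload["fixed_weights"],
        fixed_sigma2=payload["fixed_sigma2"],
        fixed_centers=payload["fixed_centers"],
        fixed_z0=payload["fixed_z0"],
    )


def chain_to_csv(chain: PosteriorChain, csv_path, sidecar_path=None) -> None:
    """Columnar CSV (one row per draw) plus a JSON sidecar with metadata."""
    import pandas as pd

    csv_path = Path(csv_path)
    K, d = chain.model.K, chain.draws[0].d
    flat = np.stack([_flatten_draw(s) for s in chain.draws])
    df = pd.DataFrame(flat, columns=_flatten_names(K, d))
    df.insert(0, "chain", chain.chain_index)
    df["log_posterior"] = chain.log_posterior_values
    df.to_csv(csv_path, index=False)
    sidecar = {
        "spec": _spec_to_dict(chain.model),
        "config": dataclasses.asdict(chain.config),
        "seed": chain.config.seed,
        "diagnostics": {k: list(v) for k, v in chain.diagnostics.items()},
    }
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def chain_from_csv(csv_path, sidecar_path=None) -> PosteriorChain:
    import pandas as pd

    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    spec = _spec_from_dict(meta["spec"])
    config = MCMCConfig(**meta["config"])
    df = pd.read_csv(csv_path)
    K = spec.K
    d = sum(c.startswith("z[1,") for c in df.columns)
    draws = []
    for _, row in df.iterrows():
        centers = np.array(
            [[row[f"z[{k + 1},{t + 1}]"] for t in range(d)] for k in range(K)]
        )
        draws.append(
            ParameterState(
                weights=np.array([row[f"pi[{k + 1}]"] for k in range(K)]),
                centers=centers,
                sigma2=np.array([row[f"sigma2[{k + 1}]"] for k in range(K)]),
                z0=np.array([row[f"z0[{k + 1}]"] for k in range(K)]),
            )
        )
    return PosteriorChain(
        draws=draws,
        log_posterior_values=df["log_posterior"].to_numpy(),
        model=spec,
        config=config,
        diagnostics={k: tuple(v) for k, v in meta["diagnostics"].items()},
        chain_index=df["chain"].to_numpy(dtype=int),
    )
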