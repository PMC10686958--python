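# rwmix

Bayesian random-walk mixture modelling and clustering of time series, aimed
at gene-expression time courses (bulk and single-cell) and other short,
noisy panels of real-valued series where the trends of interest are smooth
but of unknown shape and number.

## The model

Given a complete data matrix `X ∈ R^{n×d}` (n series, d ordered time
points), each series is an i.i.d. draw from a K-component mixture whose
component centres are latent Gaussian random walks:

    z_{k,t} ~ N(z_{k,t-1}, ε_k²)        t = 1..d   (smoothing prior)
    x_i     ~ Σ_k π_k f_k(z_k, σ_k²)               (emission mixture)

`f_k` is Gaussian by default (Cauchy, Laplace and Student-t are available),
`ε_k²` is a fixed, data-scale-dependent smoothing variance that controls
how wiggly a centre may be, and component labels are marginalised out of
the likelihood (a log-sum-exp over components per series), so no discrete
membership variables are ever sampled.

The analysis proceeds in three decoupled stages:

1. **Estimation** — each candidate model (K = 1..J) is fitted independently
   by an adaptive blockwise Metropolis-within-Gibbs sampler; chains are
   relabeled and summarised by posterior medians.
2. **Model selection** — a bridge-sampling estimate of each model's
   marginal likelihood turns the per-model chains into a model posterior
   via Bayes' theorem. Because unused components are never pruned during
   sampling, the *rectified* model posterior re-aggregates support by the
   number of components left nonempty after assignment.
3. **Assignment** — each series is scored against every centre with
   `p(x_i ∈ k) ∝ (π_k/σ_k) exp(−‖z_k − x_i‖²/(2σ_k²))`, normalised per
   series. Labels come from the argmax, optionally withheld below a
   membership-probability threshold; any other distance function can be
   plugged in, and new series can be classified against a frozen fit
   without re-running MCMC.

## Worked example

```python
import numpy as np
from rwmix import (
    CandidateSet, MCMCConfig, ModelSpec, assign_hard, clustering_accuracy,
    effective_component_count, estimate_log_evidence, membership_probabilities,
    model_posterior, permutation_matched_mse, posterior_median, rectify,
    relabel_chain, sample_posterior, simulate_doubly_stochastic,
)

# three latent walks started at -5 / 0 / +5, 90 series, 10 time points
ds = simulate_doubly_stochastic(
    ModelSpec(K=3), z0=[-5, 0, 5], eps2=0.05, sigma2=0.25,
    weights=[1/3] * 3, n=90, d=10, seed=1,
)

base = ModelSpec.for_data(ds.data, K=1, eps2=0.05)
cands = CandidateSet.nested_by_k(base, [1, 2, 3, 4, 5])
evidences, counts = [], []
for spec in cands.models:
    chain = relabel_chain(sample_posterior(ds.data, spec,
                                           MCMCConfig.preset("fast", seed=1)))
    median = posterior_median(chain)
    result = assign_hard(membership_probabilities(ds.data, median), 0.0)
    counts.append(effective_component_count(result, spec.K))
    evidences.append(estimate_log_evidence(chain, ds.data, spec).value)
    print(f"K={spec.K}  log evidence {evidences[-1]:9.2f}  nonempty {counts[-1]}")

post = rectify(model_posterior(evidences, cands), counts)
print("rectified mode:", post.selected_effective_count())

chain3 = relabel_chain(sample_posterior(ds.data, cands.models[2],
                                        MCMCConfig.preset("fast", seed=1)))
median = posterior_median(chain3)
mse, _ = permutation_matched_mse(median.centers, ds.true_centers)
labels = assign_hard(membership_probabilities(ds.data, median), 0.0).labels
print(f"centre MSE {mse:.4f}  accuracy "
      f"{clustering_accuracy(labels, ds.true_labels, 3):.3f}")
```

prints

```
K=1  log evidence  -2512.38  nonempty 1
K=2  log evidence  -1649.47  nonempty 2
K=3  log evidence   -826.62  nonempty 3
K=4  log evidence   -839.32  nonempty 4
K=5  log evidence   -853.09  nonempty 5
rectified mode: 3
centre MSE 0.0042  accuracy 1.000
```

The evidence gap of ~13 nats between K = 3 and K = 4 is the Occam penalty
for the unused component; the posterior-median centres sit within a few
hundredths (MSE 0.0042) of the realised latent walks, and every series is
assigned back to its generating component.

The same pipeline is available from the shell:

```sh
rwmix simulate --design model --k 3 --n 90 --d 10 --seed 1 --out data.csv
rwmix run --data data.csv --k-values 1,2,3,4,5 --mode fast --seed 1 --out results/
rwmix assign data.csv results/chain_K3.csv --threshold 0.5 --out assigned.csv
```

## Layout

| module | contents |
| --- | --- |
| `rwmix.model_core` | domain types, emission/prior densities, marginalised log posterior |
| `rwmix.sampler` | blockwise Metropolis-within-Gibbs, relabeling, diagnostics, chain CSV |
| `rwmix.model_selection` | bridge-sampling evidence, model posterior, rectification, K-range suggestion |
| `rwmix.assignment` | membership probabilities, thresholding, pluggable distances, realized weights |
| `rwmix.simulate` | benchmark generators and permutation-matched evaluation metrics |
| `rwmix.io` / `rwmix.pipeline` / `rwmix.cli` | matrix & counts I/O, preprocessing, pipeline orchestration, CLI |

See `docs/methods.md` for the modelling assumptions, default priors and
numerical choices.
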