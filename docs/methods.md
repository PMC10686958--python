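# Methods

## Model

The data are a complete n × d matrix of real-valued time series (rows =
series, columns = ordered time points; no missing values — the model has no
imputation mechanism). Each series belongs to one of K mixture components
with weights π (Σ π_k = 1). Component k carries a latent centre curve
z_k ∈ R^d generated by a Gaussian random walk

    z_{k,t} ~ N(z_{k,t-1}, ε_k²),  t = 1..d,  z_{k,0} = z0_k,

which acts as a smoothing prior: small ε_k² forces near-constant centres,
large ε_k² lets them bend freely. The random walk is the ρ₁ = 1, ρ₂ = 0
special case of the optional AR(1) mean process z_{k,t} ~ N(ρ₁ z_{k,t-1} +
ρ₂, ε_k²); the two log-prior code paths are verified equal at that setting.
Observations are emitted i.i.d. over time points given the centre,

    x_{i,t} ~ f(z_{k,t}, σ_k²),

with f one of Gaussian, Cauchy, Laplace or Student-t (df > 0). One
variance-like parameter σ_k² is carried per component; the non-Gaussian
families use √σ_k² as their scale, so the component covariance is always
the spherical I·σ_k² in the Gaussian case.

Component labels are marginalised analytically. The default likelihood is
the standard per-series marginalised mixture,

    Σ_i log Σ_k exp( log π_k + log f(x_i | z_k, σ_k²) ),

computed with a max-shifted log-sum-exp. A dataset-level variant — one
log-sum-exp over the component-wise sums Σ_i — is exposed as
`likelihood_form="dataset_level"`. The per-series form is the default
because it is the only form under which per-series cluster assignment is
coherent; both forms are oracle-tested against plain-arithmetic mixture
densities.

## Priors and defaults

* **Smoothing variances ε_k²** — fixed, not sampled; either one shared
  value or a per-component vector. `ModelSpec.for_data` defaults to
  0.15 × Var(X), a data-scale-dependent choice that keeps centres smooth at
  the scale of the data. Shared values keep nested candidate sets
  comparable and are required by the rectification step's nestedness check.
* **σ_k²** — half-Cauchy on σ_k with scale = SD(X) (default), expressed as
  a density on σ_k²; inverse-gamma available.
* **z0_k** — Normal(grand mean of X, 10 × Var(X)): weakly informative,
  scale-adapted.
* **π** — symmetric Dirichlet(1), i.e. uniform on the simplex,
  configurable. With ~d+1 free parameters per component this concentration
  lies in the regime where overfitted mixtures empty their extra components
  rather than duplicating occupied ones, which is what the rectified model
  posterior exploits.
* Any block can be pinned to a constant (`fixed_*` on `ModelSpec`), giving
  point-mass priors; restricted models reuse the full code path and back
  the conjugate checks below.

## Sampling

Adaptive blockwise Metropolis-within-Gibbs, self-contained (no external
probabilistic-programming dependency):

* per component, a joint Gaussian random-walk proposal on (z0_k, z_k)
  (step scaled by 1/√(d+1));
* per component, a log-scale random-walk proposal on σ_k² with the
  log-normal Jacobian in the acceptance ratio;
* one logistic-normal proposal on π: a Gaussian step on the additive
  log-ratio transform, with Jacobian Π_k π_k.

Scales adapt multiplicatively towards 35% acceptance (the middle of a
0.25–0.45 band) during warmup only; the post-warmup kernel is fixed, so
kept draws target the exact posterior. An n × K cache of per-component
emission log-likelihoods makes each block update O(n·d) ; the stored
log-posterior value of every kept draw is recomputed from scratch, which
doubles as a guard against cache drift. Chains are deterministic given the
seed (chain c uses seed + c). Presets: `fast` = 1 chain × (1000 warmup +
1000 kept), `slow` = 4 × (5000 + 5000).

Equilibrium is verified two ways: prior-only sampling of σ² reproduces the
half-Cauchy prior (KS statistic < 0.05 at 4000 draws), and on a restricted
linear-Gaussian model the sampled centre matches the analytic conjugate
posterior marginal (KS < 0.05 at 5000 draws).

**Relabeling.** The mixture posterior is invariant under component
permutations, so chains are post-processed: each draw's centres are matched
to the running mean of previously relabeled centres by Hungarian
assignment (exact for the summed-squared-distance objective; verified
against brute-force search over all K! permutations). Relabeling never
changes a draw's log posterior. It assumes exchangeable components, i.e. a
shared ε² and symmetric priors — with per-component ε_k² label switching is
not a model symmetry in the first place. Point estimates are element-wise
posterior medians (weights renormalised).

## Evidence and model selection

Each candidate model's marginal likelihood is estimated by iterative
(Meng–Wong) bridge sampling between the chain's draws and a moment-matched
Gaussian proposal in unconstrained space (identity for centres and z0, log
for σ², additive log-ratio for π, with the change-of-variable Jacobians in
the target). The fixed-point iteration runs entirely in log space; plain
importance sampling from the same proposal (`naive_is`) is retained as a
cross-check. The Monte-Carlo standard error is approximated by a two-half
split of the draws (half-difference) — crude, but adequate at the chain
lengths used and honest about its construction. A model with no free
parameters short-circuits to the exact log likelihood. Accuracy is checked
against (i) the exact stacked-Gaussian marginal of a conjugate restricted
model (free 2-point centre, all else fixed, n = 50) and (ii) 2-D grid
quadrature over the same two free parameters; both agree within 0.1 nats.

The model posterior is raw_j ∝ exp(evidence_j) × prior_j, normalised by
log-sum-exp; the model prior is uniform by default (a geometric
parsimony prior is available but off). Nonempty components are counted on
the assignment produced at the posterior-median state; the rectified
posterior transfers each model's mass to its nonempty-component count and
conserves total mass exactly. Selection reports the rectified mode, ties
broken towards the smallest count, and flags multimodality when the top
two raw probabilities are within 0.1. Rectification demands a nested
candidate set (identical structure, shared ε², strictly increasing K).

An advisory K range comes from Ward-linkage hierarchical clustering plus
the mean silhouette width (scikit-learn); it informs the candidate grid,
never the posterior.

## Assignment

Membership probabilities use the probability-scale score
(π_k/σ_k)·exp(−‖z_k − x_i‖²/(2σ_k²)) with the σ_k prefactor to the *first*
power, implemented literally; the full Gaussian-density variant (σ_k^d) is
available behind `full_gaussian=True` for sensitivity checks. Scores are
computed in log space and normalised per series, making them invariant to
common rescaling. Hard labels take the row argmax when it reaches the
threshold (applied to the normalised maximum), else the series is
unassigned (label 0); ties break to the smallest component index.
Thresholding is global by default; a per-cluster vector of cutoffs is also
accepted (applied to the winning component's probability), and
`rethreshold` re-cuts stored memberships at any new setting without any
MCMC. Euclidean, Manhattan and correlation (1 − Pearson r) distances,
or any user callable, can replace the probabilistic score; realized
weights (cluster-size fractions among assigned series) provide a secondary
estimate of π for cross-validation.

## Synthetic data

Three generators define the benchmark conditions; all are bit-reproducible
from (parameters, seed) and write a JSON truth sidecar.

* **Mixed-effects cubic design** — x_{i,j} = ξ_k(t_j) + β_i + ε_{i,j} with
  cubic-polynomial cluster trends, per-series Normal(0, 0.5²) intercepts
  and Normal(0, 0.3²) noise; defaults give 91 series in three clusters of
  31/30/30 over t = 1..10. The cubic coefficients are this package's own
  fixed choices (three visibly distinct shapes at unit data scale).
* **Function suite** — n = 100 series around a fixed registry of templates
  (linear up, linear down, sine, logistic sigmoid, constant) for K = 1..5,
  with unequal cluster sizes proportional to (K, …, 1) rounded by largest
  remainder, and Normal(0, 0.3²) noise. The registry and proportions are
  declared here as the package's own reproducible instantiation of a
  "linear + nonlinear templates, unequal sizes" design.
* **Doubly stochastic** — exact draws from the model itself: realised
  random-walk centres, categorical labels, emission noise. The standard
  recovery benchmark is K = 3, z0 = −5/0/+5, ε² = 0.05, σ² = 0.25, n = 90,
  d = 10.

These emulate the shapes, separation and noise of curated expression
panels; they do **not** emulate count-level sequencing noise,
mean–variance coupling, replicate structure, or missing data. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to real-data artefacts —
on real counts the preprocessing path (weighted log2 replicate averaging,
zero-count filtering) is the entry point and its weighting rule is a
declared approximation (below).

Evaluation resolves label switching explicitly: centre error is the
minimum over component permutations of the mean squared error (brute force
K ≤ 8, Hungarian assignment above — exact either way since the objective
separates), and clustering accuracy is the best-permutation match
fraction with unassigned counting as a mismatch.

## Preprocessing choices

Replicate-level counts are reduced to expression by
mean_r log2(s_{t,r}·count + 1). The per-measurement scale s_{t,r} equalises
the ambiguous-or-failed read fraction across measurements
(s = grand-mean fraction / measurement fraction); this is a simple,
documented instantiation of "weight so the relative failed-read share is
equal" — without read metadata s ≡ 1 with a logged warning. The
pseudocount of 1 keeps zero counts defined after the zero-count filter,
which removes exactly the genes with zero counts in every replicate at
every time point. Matrices can be read with either orientation (rows or
columns as series), since d-long profiles and n-long series are both valid
readings of the same table.

## Numerical notes and limitations

* log-sum-exp is max-shifted and returns −inf iff all inputs are −inf;
  zero mixture weights give −inf component terms, handled throughout.
* Degenerate proposal covariances in bridge sampling raise an error
  advising a longer chain (a 1e-10 ridge absorbs benign rank issues).
* Argmax/argmin ties anywhere in assignment break to the smallest index;
  posterior medians use the standard middle order statistic.
* ρ₁/ρ₂ of the AR(1) mean process are fixed spec-level values, not
  sampled; placing priors on them (and on ε²) is deliberately out of the
  sampler's block structure.
* Evidence estimates assume the relabeled chain is unimodal enough for a
  Gaussian proposal; heavily multimodal posteriors (flagged in the model
  posterior report) deserve longer chains or the slow preset.
* The problem sizes used in the shipped checks (n ≤ 90, d ≤ 10, K ≤ 5,
  fast-mode budgets) were chosen as the smallest configurations at which
  the statistical claims are comfortably testable; larger panels simply
  scale the same code paths.
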