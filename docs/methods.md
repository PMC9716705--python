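# Methods

## The model of selection

All pipelines share one statistical device. Let `y = (y_obs, y_miss)` be the
complete phenotype vector, `r` the binary missingness pattern, `θ` the model
unknowns (means, breeding values) and `φ` the parameters of the selection
rule (thresholds, an optimum). The probability of observing pattern `r`
given the phenotypes is the *fitness function*; averaging it over
`p(y_miss | y_obs, θ)` gives the expected fitness `H(y_obs, φ, θ)` that
multiplies the likelihood:

```
p_s(θ | y_obs, r) ∝ p(y_obs | θ) p(θ) H(y_obs, φ, θ).
```

When `H` does not involve `θ` or missing data, it is absorbed by the
normalizing constant: selection is ignorable. The `fitness` module turns
this into numeric checks (`check_ignorability`, invariance of grid
marginal likelihoods and posterior-predictive densities); the remaining
modules instantiate `H` for four designs.

All scalar posteriors are evaluated on a parameter grid in log space and
normalized with log-sum-exp followed by trapezoid quadrature; the correction
terms are sums of `log(1 − Φ(·))`, which underflow in linear space.

## Grid placement

A truncation correction can shift a posterior by many ignore-selection
posterior standard deviations (the shift scales with `ρ·σ·φ(τ)/(1−Φ(τ))`,
not with `σ/√m`), so a grid centred on the uncorrected mean misses the
corrected mass entirely once `m` is large. `example1_posterior` and
`harville_truncation_posterior` therefore locate the corrected-posterior
mode by bounded 1-D search over `[ȳ − 20σ, ȳ + 2σ]`, take a Laplace standard
deviation from the local curvature, and lay 2001 points over mode ± 8 sd,
stretched to also cover the uncorrected mean ± 8 sd so that the corrected
and uncorrected posteriors can be compared on one grid. Callers may always
pass an explicit grid; `fitness.default_grid` (centre ± 8 sd, 2001 points)
remains for posteriors without a selection shift.

`mean_fitness` integrates fitness × density by trapezoid, splitting the
integration cell exactly at a truncation threshold; multiplying the
indicator on grid nodes would leave an O(Δx) error at the jump.

## Relationship matrices and variance components

* `G = XX′/p`: each marker column is centred and divided by its population
  standard deviation; zero-variance columns are zeroed **and excluded from
  the divisor `p`**, keeping `diag(G) ≈ 1`.
* Pedigree `A` by the recursive tabular method after a topological sort
  (cycles are rejected); founders are unrelated and non-inbred. Validated
  against gene-dropping Monte Carlo (expected identity-by-descent).
* `nearest_psd` symmetrizes and floors eigenvalues at `1e-8` × the largest
  (relative floor): small enough not to distort printed covariance
  matrices, large enough that repaired matrices are invertible. The printed
  four-trait residual covariance has one asymmetric cell (−0.330 vs
  −0.3330); covariance matrices are symmetric by definition, so it is
  resolved by `(M + Mᵀ)/2` — the two readings give phenotypic correlations
  differing by < 1e-3.
* Single-kernel ML: with `K = UDU′` and `z = U′y` (phenotypes centred by
  their sample mean; the models carry no fixed effects), the residual
  variance profiles out in closed form, leaving a unimodal 1-D likelihood in
  the variance ratio, maximized by bounded Brent search on the log ratio over
  `[1e-6, 1e6]` with tolerance 1e-10.

## The samplers

**Pedigree pre-selection (independence Metropolis).** The target is the
GBLUP Gaussian of the selected candidates times
`Σ log[1 − Φ(z_i)]`, with
`z_i = (t − ρ_i(σ_â,i/σ_g,i) g_i) / √(σ²_â,i(1 − σ²_â,i/σ²_g,i))`.
The per-individual BLUP variance is `σ²_â,i = σ²_a A_ii − C_a[i,i]`
(reliability-based), generalizing the homogeneous-information special case
`σ_â = h²_a √(σ²_a + σ²_e)`; the correlation `ρ_gâ` defaults to a global
0.75, overridable per individual. The proposal is the pedigree-BLUP
posterior (falling back to the GBLUP posterior when no pedigree quantities
are supplied). Two acceptance modes exist: `full_mh` (default) uses the
exact Metropolis–Hastings ratio including the independence-proposal density
ratio `q(g_now)/q(g_prop)`; `as_printed` reproduces the protocol's stated
ratio verbatim — which orients the correction ratio as
`(1−Φ(z_now))/(1−Φ(z_prop))` and omits the Hastings factor — and is kept
for replication only. `full_mh` is validated against exact lattice
normalization on 3-candidate problems (total-variation < 0.05 per
coordinate).

**Multi-trait sequential culling.** Candidates are culled unless every one
of the first `T−1` phenotypes strictly exceeds its threshold; survivors are
measured for trait `T`. The joint posterior over all breeding values is

```
−½ Q_sel − ½ Q_nsel + Σ_{i culled} log Φ_{T−1}(t − g_i ; R₀ sub-block),
```

with `Q_sel` the selection-ignoring Kronecker BLUP quadratic, `Q_nsel` the
Gaussian of culled given selected breeding values, and the last term a
lower-orthant probability of the staged residuals (computed by scipy's
deterministic quasi-Monte-Carlo with a fixed internal seed, so repeated
log-posterior evaluations are identical — a requirement for a deterministic
Metropolis target; the achieved error is estimated by re-evaluating at a
smaller point budget and must be below 1e-6). The Kronecker BLUP is solved
through the eigendecomposition of `G_sel` (one `T×T` system per
eigencomponent) and is algebraically identical to the dense solve.

Four update schemes are offered. `full` and `per_trait` are independence
Metropolis with the overdispersed per-trait BLUP proposal (residual variance
inflated by `c = 2`; the proposal relationship matrix can be swapped without
touching the target, since a proposal affects efficiency only).
`per_individual` is Metropolis-within-Gibbs on each individual's `T`-vector
drawn from its exact Gaussian full conditional, so only the culling term
enters the acceptance ratio. `augmented` is a data-augmentation Gibbs
sampler: the culled individuals' staged phenotypes are retained as latent
variables constrained below their thresholds, making the model jointly
Gaussian given the latents — each sweep redraws the whole breeding-value
vector exactly (precision Cholesky precomputed) and then the latents from
truncated normals (exact for one staged trait; one inner Gibbs sweep over
the staged traits otherwise). Marginally the augmented chain targets the
same posterior (checked against importance sampling).

The augmented scheme exists because realistic genomic relationship matrices
make the joint precision extremely ill-conditioned (relatives nearly
determine one another), so single-coordinate or independence moves are
essentially never accepted beyond a few dozen individuals; block redrawing
side-steps this entirely. Chain summaries (posterior mean, sd, equal-tail
CI, split-R̂, bulk ESS via arviz) use a default burn-in of 20% of the chain.

**Nor-optimal selection.** `Γ₀⁻` is stored as the block-embedded generalized
inverse (zeros off the selected block) rather than inverting a singular
`Γ₀`; `γ = ∞` (no selection) is an explicit sentinel so the limit is exact
rather than a large float. The posterior variance of the base-population
mean uses the observed (post-selection) sample size `m`.

## Conventions and tie-breaks

* Truncation survival uses the strict inequality `y > t` (open interval);
  the boundary is measure-zero for continuous traits but is fixed for
  reproducibility.
* Stacked multi-trait vectors are trait-major, selected individuals before
  culled ones within each trait block.
* Culling-probability underflow in the multi-trait log posterior is clamped
  at `log(1e-300)` with a one-time warning.
* Every simulation and sampler takes an explicit seed and is bit-for-bit
  reproducible; CLI runs with the same `--seed` write byte-identical files.

## What the synthetic data emulate — and what they do not

The generators reproduce the *structure* of the motivating designs: a
bivariate-normal two-country system with truncation on the unobserved trait;
an inbred-line population with binary presence/absence markers (per-locus
frequencies uniform on a configurable range, effect sizes i.i.d. Gaussian on
standardized markers — the equivalent-effects model behind `G = XX′/p`; a
diploid 0/1/2 mode is available); a random-mating pedigree population with
parent-average plus Mendelian-sampling breeding values (inbreeding-adjusted
Mendelian variance); and Kronecker-covariance multi-trait phenotypes with
sequential culling. They do **not** emulate linkage disequilibrium, map
structure, multi-generation selection response, heterogeneous information
content, or fixed effects — so green tests certify the statistical machinery
under the stated Gaussian additive models, not robustness to the many ways
field data violate them. Selection counts printed for specific historical
runs are seed-specific and are reproduced in distribution, not digit by
digit.

## Problem sizes used in the test-suite protocols

Coverage of the correlated-trait design is assessed over 200 replicates of
n = 1000 pairs. The multi-trait end-to-end recovery protocol uses 200
candidates, two traits, one culling threshold at 0, a GRM built from 400
simulated markers, 20 seeds and 1500 augmented-Gibbs sweeps (burn-in 300) —
sizes chosen so the Monte-Carlo error of the posterior means is small
relative to the posterior spread. Monte-Carlo oracles use 10⁶ proposals
(moment checks at 3 MC standard errors) or 10⁵–1.2×10⁵ gene-dropping
replicates.

## Known limitations

* The pre-selection posterior conditions only on the selected candidates'
  survival; the integral over unselected candidates' breeding values is
  treated as constant (no single-step-style imputation of ungenotyped
  individuals), which discards part of the selection information.
* The multi-trait culling term is the lower-orthant probability that *all*
  staged phenotypes fell below their thresholds. With a single staged trait
  this is exactly the culling event and the corrected posterior is the
  exact Bayes posterior under the generating model; with several staged
  traits the culling event is the complement of "all above", of which the
  lower orthant is only a subset, so the term is an approximation there.
* Scalar-parameter grids only; the high-dimensional posteriors go through
  the samplers. Dispersion parameters are treated as known in all
  selection-corrected posteriors.
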