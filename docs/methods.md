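# Methods

## Model

`carst` models an area-by-year count panel `Y` (n areas, T years) with
populations `P` and expected counts `E` obtained by indirect
standardization. The observation model is NB1 negative binomial:
`Y_it ~ NegBin(mean μ_it, variance r μ_it)` with `μ_it = E_it θ_it` and
overdispersion `r ≥ 1`. "NB1" means the variance is a *multiple* of the
mean; internally this is the gamma–Poisson mixture with gamma shape
`κ = μ/(r−1)` and Poisson success probability `1/r`, which collapses to
the Poisson pmf as `r → 1` (branched below `r < 1 + 1e-8`). An NB2
variant (variance `μ + (r−1)μ²`) is available behind the
`ModelSpec(nb_variant="nb2")` flag because much software defaults to it;
the NB1 form is the package default since it matches the intended
"variance = r·mean" reading of the overdispersion parameter.

The log relative risk decomposes additively:

    log θ_it = α + U_i + V_i + γ_t + φ_t + δ_it

- `U` iid N(0, 1/τ_U): unstructured area heterogeneity.
- `V` intrinsic CAR: prior precision τ_V·R where R is the graph
  Laplacian of the contiguity graph (queen contiguity by default when
  derived from polygons). Together U+V form the BYM convolution; only
  the sum is likelihood-identified per area, so interpretation of the
  split relies on the priors.
- `γ` second-order random walk: precision τ_γ·D₂'D₂ penalizing second
  differences (locally linear trends are free).
- `φ` iid N(0, 1/τ_φ) year effects.
- `δ` one of the Knorr-Held interaction types, as the Kronecker product
  of the spatial factor (identity or Laplacian) with the temporal
  factor (identity or RW2 structure), in area-major cell ordering
  (cell (i,t) ↦ index i·T+t).

Hyperpriors: each precision carries Gamma(1, 0.001) (the conventional
"log-gamma(1, 0.001) on the log precision"). The intercept has a proper
N(0, 1000²) prior standing in for a flat one, and `log(r−1) ~ N(0, 10²)`
is weakly informative — chosen so the Poisson boundary r = 1 is
approachable but not favored.

## Constraints and parameterization

The intrinsic structures are rank deficient: ICAR has one null vector
per connected component, RW2 two (constant + linear), and the Kronecker
interactions inherit products of the factor null spaces (e.g. Type IV
on a connected graph has rank (n−1)(T−2)). Instead of soft constraints
or post-hoc recentring, every deficient block is parameterized on an
orthonormal eigenbasis of its structure's row space: `x = K ξ` with
`K'RK` diagonal (the nonzero eigenvalues). Consequences:

- sum-to-zero and detrending constraints hold to machine precision at
  every iteration, by construction;
- the reduced prior on ξ is proper, with the rank-adjusted normalizing
  constant used verbatim in `log_posterior`;
- the MCMC target is exactly the constrained posterior — no
  approximation from recentring between sweeps.

`γ` is constrained orthogonal to both the constant *and* the linear
trend (its full null space). A global linear time trend therefore lives
in `φ` (which, being iid, can realize any temporal shape at a prior
cost) rather than in `γ`; `γ` captures curvature. This is a deliberate
choice: leaving the linear direction unpenalized inside `γ` would make
its reduced prior improper.

A documentation note on interaction types: descriptions circulate in
the applied literature that label the Type II interaction (iid space x
structured time) as "iid normal". Structurally it is not — its prior is
I_n ⊗ RW2 with rank n(T−2) — and this package implements the standard
structured form for Types II, III and IV; only Type I is fully iid.

## Sampler

Blocked Metropolis-within-Gibbs:

- Each latent family (α, U, V, γ, φ, δ) updates jointly from a Gaussian
  approximation of its full conditional: second-order IWLS expansion of
  the log-likelihood in the linear predictor (score from digamma terms
  for NB1, working weights μ/r; y−μ and μ for Poisson), combined with
  the reduced prior precision τK'RK. The proposal is corrected by a
  Metropolis-Hastings ratio with the reverse proposal rebuilt at the
  proposed point, so the exact posterior is targeted even where the
  quadratic approximation is imperfect. For iid blocks the proposal
  precision is diagonal; for the interaction block the weighted
  cross-product K'WK is assembled through the Kronecker factors.
- Precisions are conjugate: τ_f | ξ_f ~ Gamma(1 + rank/2, 0.001 + q/2)
  with q the structure quadratic form.
- `log(r−1)` moves by a random-walk Metropolis step whose scale adapts
  toward ~40% acceptance during burn-in only (retained draws are from a
  fixed-kernel Markov chain).

Defaults for full-size problems are 2 chains × 3000 iterations with
1000 burn-in and thinning 2; the test and acceptance runs use smaller,
stated values (typically 2 × 900/400 for scaled-down fits and 1 × 500
for comparison fits) — the IWLS proposals mix near-iid on those sizes.
Split R-hat and effective sample size (via arviz) are attached when at
least two chains are run. All randomness flows from one seed through
named, hashed child streams (`carst.panel_io.child_seed`).

Numerical guards: the linear predictor is clipped at ±40 before
exponentiation; working weights are floored at 1e-10; a non-finite
predictor aborts the run with a state dump in the error message.

## Exploratory statistics

Global Moran's I uses `I = (n/S0)·(z'Wz)/(z'z)` on centered values with
binary or row-standardized contiguity weights (row-standardized
default). Significance is by full-vector Monte-Carlo permutation,
one-sided toward positive autocorrelation, `p = (1 + #{I* ≥ I})/(M+1)`.
Local Moran uses conditional permutation (each area's value held fixed,
its neighbors resampled from the remaining areas), one-sided in the
direction of the observed local statistic, with High-High/Low-Low/
Low-High/High-Low quadrants from the signs of (z_i, lag_i) and a 0.05
significance default without multiplicity correction (an FDR-minded
user can lower alpha); this mirrors common LISA mapping practice.

## Model evaluation

- DIC with the classic effective-parameter form pD = mean deviance −
  deviance at the posterior-mean state; `half_variance=True` switches to
  pD = var(deviance)/2, since software defaults differ.
- WAIC from the stored per-cell per-draw log-likelihood matrix
  (log-mean-exp lppd; pW = sum of pointwise variances).
- Variance fractions: empirical variance of each family's
  posterior-mean effect values over its index set, normalized to sum to
  one. The overdispersion row is the mean per-cell `trigamma(κ)` — the
  variance of the latent log-gamma mixing noise — an explicit
  convention, since several incompatible definitions are in use.
- Exceedance probabilities `P(component > threshold)` per cell with the
  conventional 0.2/0.8 mapping bands; posterior relative-risk surfaces
  binned into [0, 0.5), [0.5, 0.95), [0.95, 1.05), [1.05, 1.5), [1.5, ∞)
  (left-closed, matching the "0.95 to less than 1.05" reading).
- One-year-ahead prediction per retained draw: γ continues by its RW2
  conditional (2γ_T − γ_{T−1} + innovation at the drawn precision), φ by
  a fresh iid draw, and δ by policy — RW2 carry-forward per area for
  types II/IV (default), fresh iid draw for I/III, or a "freeze" policy
  that plugs in the final year's values unchanged (the literal reading
  of prediction "conditional on posterior means"). Counts are then
  sampled from the NB1 observation model. The mechanism used is
  recorded in the output since the right continuation is genuinely
  underdetermined for intrinsic interactions.

## Synthetic data

`simulate_effects` draws every latent family exactly from its
(constrained) prior by spectral decomposition — standard normals scaled
by 1/sqrt(τλ_k) along the nonzero eigendirections — so the truth
satisfies all constraint sets to machine precision and matching-model
fits are a clean test of the inference. `simulate_panel` turns a latent
state into counts through the same NB1 observation model, with
`E = population × reference_rate`.

Because intrinsic structures have strongly uneven implied marginal
variances, generator effect sizes are stated as *typical marginal
standard deviations* and converted to precisions via the geometric mean
of the structure's pseudo-inverse diagonal (`marginal_precision`); for
Kronecker structures that diagonal is the Kronecker product of the
factor diagonals.

The 262-area fixture (`elsalvador_like_fixture`) is a 16×17 queen
lattice with 10 cells removed, T = 20, log-normal populations (median
12k, log-sd 1.2, floored at 2.5k), baseline rate 5.3 per 10,000,
marginal effect sds (U, V, γ, φ, δ) = (0.10, 0.15, 0.20, 0.10, 0.35)
with a dominant Type IV interaction, and r = 3. These values were
calibrated so per-year zero-count shares fall around 10–30% and crude
rates span roughly 0–100 per 10,000 — the regime of a national
small-count homicide panel. The fixture is explicitly synthetic: it has
no geographic fidelity, its populations are static over time, and its
adjacency is a lattice, so passing tests demonstrate correctness of the
machinery under realistic count sparsity, not conclusions about any
real place.

## Scaled-down study sizes

Recovery and model-selection experiments run on a 6×6 rook lattice over
8 years (288 cells), 20 replicates in the test suite and 10 in the
acceptance script, with 2×900 (burn 400) sampler sweeps for recovery
fits and 1×500 (burn 250) for comparison fits. These sizes give
near-iid mixing for the IWLS proposals while keeping a full study in
minutes; coverage checks use a conservative binomial band around the
nominal 90% level.

## Known limitations

- The sampler's dense reduced bases are comfortable up to a few
  thousand interaction cells; the full 262×20 Type IV posterior is an
  hours-long single-CPU job and is wired as an optional long-running
  test rather than part of the desk-scale suite.
- U and V are only jointly identified; reported component splits are
  prior-driven.
- Expected counts use a single (panel-pooled by default, optionally
  per-year) reference rate; no age/sex standardization.
- Prediction beyond one year ahead, and formal posterior-predictive
  p-values, are out of scope.
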