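# Methods

## The model

Each testing unit *i* (a peptide probe, a gene, a metabolite, ...) is reduced
to two summary statistics: an estimated effect *x_i* and its squared standard
error *s_i²*. The sampling model is the standard normal-theory pair

- *x_i* | θ_i, σ_i² ~ Normal(θ_i, σ_i²),
- ν·s_i²/σ_i² | σ_i² ~ χ²_ν,

with degrees of freedom ν fixed by design (n₁ + n₂ − 2 in the two-group
comparison) and shared by all units. The latent parameters are drawn from a
product of two discrete mixing distributions:

- **g** on a regular effect grid a₋K, …, a₀, …, a_K with the presumed mode
  a₀ (the null value, 0 by default). g is constrained to be unimodal at a₀:
  g_k ≤ g_{k+1} left of the mode, g_k ≥ g_{k+1} right of it. The null
  proportion is π₀ = g at a₀.
- **h** on a regular positive variance grid b₁, …, b_L, unconstrained beyond
  the simplex.

Estimating a mixing distribution over variances — rather than plugging in
s_i² — is what distinguishes the method from one-layer adaptive-shrinkage
approaches; with modest ν the difference between s_i and σ_i is substantial
and ignoring it distorts both π₀ estimates and error rates.

Both mixing distributions are estimated jointly by maximizing

    l(g, h) = Σ_i log Σ_k Σ_l g_k h_l p(x_i | a_k, b_l) p(s_i² | b_l)

over the product of the two simplices subject to the unimodal ordering
constraints. From the fitted (ĝ, ĥ), each unit gets a posterior over the
effect grid,

    P(θ_i = a_k | x_i, s_i²) ∝ ĝ_k Σ_l ĥ_l p(x_i | a_k, b_l) p(s_i² | b_l),

from which we report

- **lfdr_i** = P(θ_i = a₀ | data) — the local false discovery rate, and
- **lfsr_i** = min{ P(θ_i ≤ a₀ | data), P(θ_i ≥ a₀ | data) } — the local
  false sign rate (both cumulative sums include the mode atom, so
  lfdr ≤ lfsr ≤ (1 + lfdr)/2 always).

Discovery lists are {i : statistic_i ≤ c}; the mean lfdr over a list
estimates its realized false-discovery rate and is reported alongside it.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| K | 15 | effect grid has 2K+1 = 31 points; finer grids mainly cost compute |
| effect half-width | max_i \|x_i − mode\| | the grid must contain every estimate; no padding |
| L | 10 | variance grid size; resolves the observed s² range while keeping the m×31×L tensor small |
| variance grid span | [min s², max s²] | linear spacing; constant input padded ±5% |
| mode | 0 | the null value; nonzero modes supported |
| ν | n₁+n₂−2 | design-based; a single scalar — per-unit ν is rejected, not averaged |
| tol | 1e−8 | relative objective change declaring convergence |
| subsample_fraction | 1.0 | optional likelihood subsampling for very large m (seeded) |

## Optimization

The objective is smooth with analytic gradients but not jointly convex in
(g, h) (it is concave in each argument separately). The solver is:

1. **EM warm start** — multiplicative responsibility updates with an
   order-restricted M-step for g. The unconstrained M-step weights are the
   average responsibilities; the unimodal M-step is their isotonic
   regression under the unimodal partial order (computed by Dykstra's
   alternating projections between the two chain cones, each solved by
   PAVA). This makes every iterate feasible and the likelihood monotone, and
   it handles boundary optima (mass exactly zero on grid points) gracefully.
2. **SQP polish** — SLSQP on the concatenated vector with the two simplex
   equalities, 2K ordering inequalities and box bounds, wrapped in an outer
   loop that stops when the relative objective change falls below `tol`.
3. **Projection at return** — clip, a mode-outward monotonicity sweep and
   renormalization remove residual violations (bounded by the solver's own
   violation, ~1e−12 in practice); final constraint violation is reported
   and is required to be ≤ 1e−8.

The returned objective never falls below the uniform starting point (the
best-seen iterate is kept; solver failures are reported via
`converged=False`, never raised). A brute-force simplex-mesh enumerator over
tiny grids provides an independent optimizer oracle in the tests; the solver
must attain at least the mesh optimum (a mesh necessarily trails the
continuous optimum, so agreement is one-sided by construction).

No multi-start is attempted by default; on the scenarios exercised here,
random restarts and the EM/SQP route agree to ~1e−3 log-likelihood units.

## Synthetic data

The generator mirrors the standard operating-characteristic benchmark for
effect-shrinkage methods: θ_i ~ π₀·δ₀ + (1−π₀)·g_alt with named alternative
shapes (all normal mixtures, config-overridable):

- spiky: 0.4·N(0,0.25²) + 0.2·N(0,0.5²) + 0.2·N(0,1) + 0.2·N(0,2²)
- near_normal: (2/3)·N(0,1) + (1/3)·N(0,2²)
- flattop: equal mixture of seven N(μ, 0.5²), μ ∈ {−1.5, …, 1.5}
- big_variance: N(0,4²)
- bimodal: 0.5·N(−2,1) + 0.5·N(2,1)

Latent observation variances come from a point mass (default σ² = 1), a
two-point mixture (0.5/2.0, equal weights) or an inverse-gamma (shape 5,
scale 4; mean 1). The two-point and inverse-gamma parameter values are our
choices — the benchmark literature names only the families. Per unit, two
groups of `n_per_group` Gaussian observations are drawn and summarized by
the same two-group code path used for real data (pooled variance,
ν = 2n − 2). The harness draws π₀ ~ Uniform[0.5, 1] per replicate unless
fixed, and aggregates empirical FDR, π₀ recovery and the 1-Wasserstein error
of ĝ inside the four strata [0.5, 0.625], [0.625, 0.75], [0.75, 0.875],
[0.875, 1].

What the generator does **not** emulate: heavy-tailed or skewed intensity
noise, correlation between units (array spatial effects, shared subjects),
unit-specific degrees of freedom, and preprocessing artifacts. A green
simulation test therefore establishes calibration under the normal-theory
sampling model, not robustness to its violations.

## Numerical choices

- All density work is in log space; per-unit maxima are factored out before
  exponentiation, and a density floor of 1e−300 guards log(0) while the
  solver probes the boundary. −∞ log-densities propagate without NaN.
- Grids are validated to be regular within relative 1e−9; the effect grid's
  middle point equals the mode exactly (set, not computed).
- lfsr at x = 0 with a symmetric posterior: both signed sums are equal, the
  min is well defined, no tie-break is needed. lfsr is clipped up to lfdr
  to absorb last-digit rounding.
- The reproducibility overlap of two empty lists is reported as missing
  (NaN), not 0 or 1.
- Thresholding is inclusive (statistic ≤ c). Raw per-unit thresholding is
  primary; no cumulative-mean re-ranking is applied.
- Numeric table output uses %.17g and round-trip float parsing, so written
  results re-read bit-identically.

## Known limitations

- π₀ is identified only as an upper bound from limited data; when g_alt
  concentrates near 0 (the spiky shape) or when the per-unit standard error
  is large relative to the grid spacing, the MLE can trade mode mass
  against neighboring grid points nearly flatly. At n = 10 per group this
  produces a visible downward spread of π₀ estimates for the flattop shape;
  the bias disappears as n grows (the estimator is consistent — exercised
  by the test suite). Alternatives concentrated on a few well-separated
  points conflict with the unimodality constraint and drain the strict mode
  atom further (shelf mass); the mass within one grid cell of the mode is
  then the better-behaved summary.
- The likelihood is not jointly convex; the solver returns its fixed point.
  Tests compare objectives and posterior outputs rather than raw (g, h),
  which are non-identifiable at equal likelihood.
- The chi-square layer for s² is exact under Gaussian data only;
  transformed intensity data (double-log) make it a reasonable
  approximation, but ν estimation for non-normal data is out of scope.
- Comparison baselines (BH, q-value, one-layer shrinkage variants) are not
  reimplemented here.
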