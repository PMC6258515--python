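# Methods

This note records the model behind the package, the choices made where the
method's published description leaves room, and what the simulation-based
tests do and do not establish.

## The data-generating process

All calibration and evaluation run on simulated spatial autoregressive
(SAR) variables on regular rook-contiguity lattices:

```
y = ρ W̃ y + ε,    ε ~ i.i.d. N(0, 1),
```

solved as `y = (I − ρW̃)⁻¹ ε` by sparse LU factorization (one factorization
per (W, ρ), reused across draws).  `W̃` is the **row-standardized**
contiguity matrix (`w̃_ij = 1/deg(i)` for neighbors).  Row standardization
is a deliberate choice: it makes the process stable for every ρ strictly
inside (−1, 1), because the spectrum of `W̃` lies in [−1, 1] (on a bipartite
lattice both endpoints are attained).  The noise law is not dictated by the
method; standard normal noise with no intercept is used because the effect
metrics and the statistic are scale-free.  Mean zero and variance one are
therefore conventions, not assumptions.

`SpatialWeights` admits exactly two sources — generated rook lattices and
GAL files — because the method consumes contiguity, never geometry.  GAL
reading is strict about symmetry by default; `strict=False` symmetrizes
with a warning, since silently repairing an asymmetric file hides data
errors.

## Estimating ρ

ρ̂ maximizes the concentrated log-likelihood of the spatial-lag model

```
ℓ(ρ) = ln|I − ρW̃| − (n/2)·ln(SSE(ρ)/n)
```

with the log-determinant evaluated through the (real) eigenvalues of `W̃`
and SSE the residual sum of squares of `(I − ρW̃)y` **with the intercept
concentrated out** (i.e., the residual is mean-centered; equivalently the
model includes a constant).  The intercept matters: a constant vector is
not in the null space of `I − ρW̃`, so the intercept-free likelihood is
badly biased toward 0 for any variable whose sample mean is far from zero —
in particular for redistributed variables that inherit the sample mean of
their source draw.  With the intercept, ρ̂ on direct SAR draws is unbiased
to within Monte-Carlo error at the lattice sizes used here (verified in the
test suite against a 10⁻³-step grid search of the same likelihood).
Optimization is a coarse 67-point grid bracket followed by bounded scalar
minimization on the bracket, over (−0.99, 0.99).

## Redistribution to a target ρ

To compare MAUP effects across autocorrelation levels without confounding
them with different value multisets, a single SAR(0.9) draw supplies the
values and each other level is produced by **rank matching**: draw an
auxiliary SAR(ρ_target) pattern, give the highest value to the location of
the pattern's highest value, and so on (ties broken by area id; probability
zero for continuous draws).  The candidate is accepted iff
`|ρ̂ − ρ_target| ≤ 0.1`; otherwise a fresh pattern is drawn, up to
`max_attempts` (default 100).  Rank matching preserves the multiset — and
hence mean and variance — exactly.  At very small N (25 areas) the achieved
ρ̂ for strongly negative targets is attenuated (the multiset's magnitudes
cannot reproduce an extreme alternating pattern), so acceptance may take
tens of attempts there; failures raise an error reporting the best gap
achieved.

## Random contiguous aggregation

`grow_regions` draws k distinct seed areas uniformly, then repeatedly picks
uniformly among unassigned areas adjacent to at least one growing region
and assigns the area to a uniformly chosen adjacent region.  Any
contiguity-preserving uniform growth scheme serves the method's purpose
(random aggregations); this variant was chosen because it is unbiased,
terminates on every connected graph, and guarantees exactly k non-empty
connected regions (fuzz-tested against an independent graph-connectivity
oracle).  Region values are **unweighted** means of member areas — the
defining behavior of spatially intensive variables.  Batch draws derive
per-replicate sub-seeds deterministically from a master seed.

## Effect metrics and the location shift

For one aggregation, `RCM = |μ_o − μ_ag| / μ_o` and
`RCV = |σ²_o − σ²_ag| / σ²_o` (population variances; both sides use the
same convention, so the choice is immaterial).  Per instance these are
averaged over r = 30 aggregations.  One numerical caveat is handled
explicitly: with a strictly mean-zero simulated variable, μ_o ≈ 0 and the
RCM denominator is meaningless.  Real spatially intensive variables (rates,
densities) are positive, so `effect_experiment` adds a constant location
shift (default 10, i.e. ten noise standard deviations) before computing the
mean-based quantities.  Variance-based quantities, the Levene test, the
t-test decision, and ρ̂ are all location-invariant, so the shift affects
nothing but the RCM denominator.  The default grid is the full design
(N ∈ {25, 100, 225, 400, 625, 900} with their printed k-sets, nine ρ
levels, 50 instances, 30 replicates); scaled-down runs shrink the instance
count, never the replicate count.

The variance check is the classical **Levene test** (mean-centered absolute
deviations; `scipy.stats.levene(center='mean')`), not the median-centered
Brown–Forsythe variant.  The mean check is the **Welch** two-sample t-test,
chosen because unequal variances between the original and aggregated
samples are precisely the phenomenon under study.  Comparing the N original
values against the k aggregated values treats two dependent samples as
independent; this conservatism is part of the procedure being reproduced
and explains the near-zero t rejection rates.  The Monte-Carlo engines use
closed-form fast paths for both tests (via `scipy.special`), asserted
identical to the public functions at 10⁻¹² in the suite.  The t-test pool
is restricted to k ≥ 10 (tiny aggregated samples make the t-test
uninformative); the Levene pool is not.

## The statistic and its null

`M(ρ, θ) = L(θ) / (1 + η(θ)·e^{τ(θ)ρ})` with the six calibrated constants
b = −2.188, m = 7.031, p = 0.516, a = 1.287, β₀ = 5.319, β₁ = −5.532.
M is strictly within (0, L(θ)) ⊂ (0, 1), strictly decreasing in θ at every
ρ, and strictly decreasing in ρ for θ below τ's root at θ ≈ 0.9615
(direction reversing above it) — all grid-asserted in the suite.  In
applied use the ρ plugged in is the ML estimate ρ̂ (a practitioner has no
true ρ); simulation experiments default to the generator's ρ label, which
is how the reference critical-value and power tables are indexed.  Both
modes are switchable (`use_estimated_rho`).

Null distributions are built by rejection sampling: draw SAR(N, ρ), draw k
uniformly on the integers with `0.1N < k < N` (a literal reading:
⌊0.1N⌋+1 … N−1), make 30 random aggregations, and retain the instance only
if the Levene test is non-rejected in **all** 30 — the operational meaning
of "the variable is not sensitive at this k".  Retained instances yield
`M(ρ, k/N)`; the critical value is the empirical (1−α) percentile.  The
pseudo-p of an observed M is the strict exceedance fraction of the null
vector (the reference definition fixes J = 1,000 draws; the implementation
uses the actual null length).

Critical values for applied use come from a packaged 9 × 3 × 6 table
(ρ × α × N).  Off-grid ρ is linearly interpolated between bracketing rows
(clamped at ±0.9); off-grid N snaps to the nearest tabulated N (ties toward
the smaller, i.e. more conservative at matched ρ ≥ 0 patterns); a
`conservative` policy takes the larger bracketing cell instead.  The policy
used is recorded in every result because the published table is silent on
interpolation.

## Power, size, and what reproduces

Power runs keep instances where all 30 Levene tests **reject** (the
alternative demonstrably holds) and report the fraction whose M exceeds the
tabulated critical value; size runs use the complementary selection.  At
α = 0.05 the three gated cells reproduce the reference power values
(≈ 0.99–1.0) within Monte-Carlo tolerance.  The published size table
reproduces only weakly against the packaged critical values — the reference
null vectors were produced by unreleased code at a scale this package does
not re-run — so size is gated only through self-consistency: with the
critical value taken as the 95th percentile of a null from this package's
own generator, the measured size is 0.05 within Monte-Carlo error, which is
the property a percentile threshold must have.  Published example tables of
M values for specific (N, k, ρ) triples are likewise not reproducible by
direct evaluation of the statistic with the printed constants (checked at
several rows; discrepancies are non-systematic); only their reject /
non-reject decisions are used as test examples.

## Recalibrating the constants

`fit_components` re-runs the calibration pipeline on a grid of median
RCV̄ values indexed by (ρ, θ): (1) per-θ nonlinear least-squares fit of the
three-parameter inverted logistic in ρ; (2) robust (Huber IRLS) linear fit
of the logit of L against θ, giving b and m; (3) robust log-log fit of η
against θ, giving p and a; (4) robust linear fit of τ against θ, giving β₀
and β₁.  One deliberate departure from the obvious reading: L is *fitted*
per curve rather than read off as the curve's maximum over the ρ grid,
because at large θ (τ ≈ 0) the curve has not plateaued at ρ = −0.9 and its
maximum underestimates the asymptote by up to ~40%, which would bias b and
m by several percent even on noiseless data.  With the fitted-L pipeline,
recovery from a noiseless synthetic surface is exact to ≲10⁻⁸ and stays
within 5% under 1% multiplicative noise (both asserted).  A full-scale
refit of the constants from fresh effect grids at the published experiment
size is out of scope; `smaup calibrate` performs the reduced-scale version
on any effects table.

## What the simulations do and do not establish

The synthetic world is Gaussian SAR on regular rook lattices.  It emulates
the two drivers the method is built on — spatial autocorrelation and
aggregation level — but not irregular adjacency structures (the statistic
is explicitly calibrated for mean degree ≈ 4), covariates, heavy-tailed or
skewed marginals, population-weighted dissolves, or zoning effects beyond
what M encodes.  A green suite therefore establishes internal correctness
and reproduction of the reference Monte-Carlo behavior on lattices, not
validity of the test for weights matrices far from lattice-like.

## Numerical details worth knowing

- Population variances (ddof = 0) everywhere in the effect metrics.
- Degenerate two-sample tests (zero spread in both samples) return p = 1 by
  convention rather than NaN.
- Rank ties in rank matching break by area id (stable sort).
- Seeds: every stochastic operation takes an integer seed, a SeedSequence,
  or a Generator; batch operations spawn counter-derived sub-seeds so no
  stream is reused; all seeds appear in reports.
- The eigendecomposition used by the ML estimator is dense and cached per
  weights object (O(n³) once; fine to N ≈ 2,500, the intended regime).
- `generate_null` and the power/size engines short-circuit their Levene
  loop on the first disqualifying replicate and raise with acceptance-rate
  diagnostics if the rejection-sampling budget is exhausted.
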