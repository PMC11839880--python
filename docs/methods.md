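# Methods

This note records the statistical models implemented in `distfree`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Conjugate beta inference

All Bernoulli-type analyses share one engine.  A Beta(a₀, b₀) prior on a rate
φ and counts (n₁, n₂) give the posterior Beta(a₀+n₁, b₀+n₂).  Default priors
are uniform (a₀ = b₀ = 1, maximum-entropy); a Jeffreys prior is obtained by
passing a₀ = b₀ = ½.  Descriptives:

- mean a/(a+b), variance ab/((a+b)²(a+b+1));
- median via the inverse regularized incomplete beta (never sampling);
- mode (a−1)/(a+b−2) only when a > 1 and b > 1, otherwise flagged undefined;
- equal-tail interval from the quantile function at (1−p)/2 and 1−(1−p)/2;
- HDI by minimizing interval width over the lower-tail mass with bounded
  scalar optimization (xatol 1e−10).  The width is unimodal for a unimodal
  density, so the bounded search is reliable.  When exactly one shape
  parameter is ≤ 1 the density is monotone and the HDI is one-sided
  ([0, q_p] or [q_{1−p}, 1]); when both are ≤ 1 (flat or U-shaped density)
  it is reported undefined rather than guessed.

Bayes factors: interval nulls use posterior/prior odds from incomplete-beta
masses.  Point nulls use the Savage–Dickey density ratio (posterior density
over prior density at the null point) — the standard choice for a point null
nested in a continuous prior; no other definition is implied by the
interval/point API split.  When a hypothesis mass underflows to exactly 0
the Bayes factor is reported as `inf` (serialized as the string `"inf"`),
never as a large finite sentinel.

## Categorical tests

- **McNemar**: posterior for the switching rate φ_rb from (n₀₁, n₁₀); the
  descriptive chi-square (n₀₁−n₁₀)²/(n₀₁+n₁₀) uses no continuity correction.
  With zero switches the prior is returned unchanged and the chi-square is NaN.
- **Sign test**: zero differences are dropped under exact floating-point
  comparison and reported as `n_zero_dropped`.  Users whose pipelines produce
  near-zero differences from rounding noise should threshold before calling.
- **Median test**: the combined median of an even-sized pool is the midpoint
  of the two central order statistics (the standard convention); observations
  are counted only when *strictly above* it, so median-tied scores never count
  toward the E side.  The null is φ ≤ n_E/(n_E+n_C); its prior mass is
  computed from the prior beta at the base rate, not assumed ½.

## Contrasts of K beta variates

Weights must satisfy Σψᵢ = 0, Σψᵢ⁺ = 1, Σψᵢ⁻ = −1 to tolerance 1e−10.
E(Δ) and V(Δ) are the closed-form weighted moments of the K posterior betas.
The Monte Carlo posterior draws `samples` values per condition (default
10000), forming Δⱼ = Σᵢ ψᵢ φᵢⱼ.  Numerical choices:

- interval estimates are equal-tail empirical quantiles with type-7 linear
  interpolation (deterministic given the sample);
- the prior probability of Δ > 0 is estimated by the same sampling scheme on
  the prior betas rather than assumed ½, since non-uniform priors shift it;
- a binomial standard error for P(Δ > 0) is reported so users can judge
  seed-to-seed variability;
- if no prior draw (or no posterior draw) falls on one side of zero, BF₁₀ is
  reported as 0 or `inf` according to the direction of the evidence.

## Rank-statistic posteriors

**Grid.**  Both small-sample algorithms use the 200-point grid .0025, .0075,
…, .9975 (step .005, never touching .5, so P(parameter > .5) is a clean grid
sum).  The prior on the grid is the beta density evaluated at the grid points
and normalized over the grid (bin-integration would differ only at O(step²)).

**Wilcoxon small-n** (auto-selected for n ≤ 24 blocks): at each grid value φ
the ranks 1..n receive independent positive signs with probability φ
(`samples` draws, default 30000); the likelihood is the fraction of sampled
T⁺ equal to the observed T⁺.  The observed T⁺ is rounded to the nearest
integer before matching because midranks from tied |d| can make it
non-integer while the sampler's support is integer.  If the rounded statistic
is unreachable the function raises and advises the large-sample method.

`wilcoxon_exact_posterior` evaluates the same likelihood exactly by dynamic
programming over the generating function Π_r((1−φ) + φ z^r).  It is the
samples→∞ limit of the sampler, is deterministic, and is what the power
simulator uses on small paired samples (a 200-grid × 30000-draw Monte Carlo
run per replication would make power tables impractical; the DP version is
mathematically equivalent and error-free).

**Mann–Whitney small-n** (auto-selected when the harmonic mean of the group
sizes is ≤ 19): the two groups are simulated from exponential distributions
with rates (1−Ω) and Ω, a pair whose dominance probability is exactly Ω; the
likelihood is the fraction of sampled U_E matching the observed (rounded)
U_E.  Matching is on U_E alone; under cross-group ties the observed U_C
carries no extra information for this sampler.  The comparison tensor is
chunked to bound memory.

**Large-sample approximation** (n > 24, or harmonic mean > 19): a normal
approximation to the sampling distribution of the statistic is evaluated on
the grid — T⁺ ~ N(φ n(n+1)/2, φ(1−φ) n(n+1)(2n+1)/6) for the Wilcoxon;
U_E ~ N(Ω n_E n_C, v) for the Mann–Whitney, where v is calibrated once per
group-size pair by a 10⁴-draw pilot of the exponential-construction sampler
at Ω = .5 (fixed internal seed, cached) and scaled by Ω(1−Ω)/.25.  The grid
posterior is then moment-matched to a beta distribution and all summaries
come from that fitted beta.  This fit is validated behaviorally against the
exact small-sample posterior (quantiles within .02 at n = 20) rather than by
reproducing any particular closed-form shape parameters.  The boundary is
deliberately `harmonic mean > 19` and can be overridden with
`method="small"`/`"large"`.

Equal-tail intervals from a discrete posterior linearly interpolate the step
CDF between adjacent grid points.  Progress through the 200-point loop is
emitted through the `logging` module and suppressed by `quiet=True`.

**K > 2 conditions.**  `composite_pair` builds Y1 from the positive-weight
columns and Y2 from |ψ|-weighted negative columns of a blocks×K matrix;
`pool_groups` concatenates positive-side and negative-side groups.  Both
inherit the contrast-weight constraints.

## Power simulation

`sim_data` draws condition C from the chosen model with parameter `shape1`
and condition E from the model with `shape2` plus the location shift δ.
Parameterizations: normal sd = shape; Weibull shape parameter with unit
scale; Cauchy scale with location 0; lognormal sdlog with meanlog 0;
chi-squared df; logistic scale; exponential rate; Gumbel scale with location
0; Pareto tail index with minimum 1.  Block effects add a Uniform(0,
block_max) draw to both members of a pair (cancelling exactly in difference
scores) or independently to each observation of the independent design.

Each replication is analysed with the Bayesian rank posterior (Wilcoxon for
paired, Mann–Whitney for independent, with the automatic method selection
above) and with the classical t test (paired, or pooled-variance two-sample).
The t p-value is **one-sided** (upper tail, testing the E > C direction),
matching the one-sided Bayesian criterion P(parameter > .5) ≥ `effect_crit`;
the implied frequentist α is 1 − `effect_crit`.  Under a symmetric null both
detection rates calibrate to α.

`bayes_vs_t_power` evaluates 11 sample sizes n_min..n_min+50 (step 5);
`power_curve` evaluates 21 separations 0..20·delta_step.  Default 1000
replications per cell; per-cell generators are spawned from the root seed via
`SeedSequence` so cells are independent and the whole table is reproducible
bit-for-bit.  The test suite and acceptance script run these simulators at
300–10⁴ replications per cell, sizes chosen to keep Monte Carlo error well
inside the tolerances being checked.

**What the generator emulates — and does not.**  The nine models cover
light-tailed, skewed, heavy-tailed, and pathological (Cauchy) measurement
error, with independent observations and, optionally, additive uniform block
effects.  Real data can violate what remains assumed: exchangeability within
condition, additivity of the block effect, a pure location-shift treatment
effect, and absence of serial correlation.  Passing power and calibration
checks therefore demonstrates correctness of the algorithms under these
stated conditions, not robustness to every failure mode of real designs.

## Association

The concordance kernel is the O(N²) exhaustive pair loop (vectorized sign
comparison on raw values — rank transformation is unnecessary because signs
of differences are rank-invariant).  Tie totals T_X, T_Y, T_XY are
Σ t(t−1)/2 over tie clusters; the identity n_c + n_d = N(N−1)/2 − T_X − T_Y
+ T_XY is enforced at construction, so inconsistent hand-built counts are
rejected.  τ_A intervals are the monotone map 2q − 1 of φ_c quantiles.  The
goodness-of-fit adjustment subtracts Nm − m(m+1)/2 from n_c (never from n_d)
and rejects over-parameterized models where n_c* ≤ 0; m counts the total
free parameters over all fitted units.  τ_B is deliberately not offered: it
understates association under ties (the test suite carries a regression
demonstrating the flaw).

## Design choices that were genuinely open

- **Point-null Bayes factor formula**: Savage–Dickey (documented above).
- **Contrast interval type**: equal-tail from empirical quantiles.
- **Quantile convention**: type-7 linear interpolation.
- **Tie handling in the rank samplers**: observed statistics rounded to the
  integer support; matching on U_E only.
- **Harmonic-mean cutover**: strictly greater than 19.
- **One-sided t convention** for power comparisons (documented above).
- **Median-of-even-pool**: midpoint convention; strictly-above counting.
- **Power-simulator small-n path**: exact DP likelihood instead of per-replication
  Monte Carlo (equivalent distribution, no MC error, tractable cost).

## Known limitations

- The large-sample Mann–Whitney variance calibration is itself a Monte Carlo
  pilot; its cache is keyed by group sizes and uses a fixed internal seed, so
  results are reproducible but carry a small, shared approximation error.
- The small-sample Mann–Whitney sampler is O(grid × samples × n_E × n_C);
  with the default 30000 samples it is meant for the group sizes where it is
  auto-selected (harmonic mean ≤ 19).
- Grid posteriors cannot resolve parameter values beyond the .005 grid step;
  intervals inherit that granularity.
- Exact-zero detection in the sign test and tie detection elsewhere use
  floating-point equality by design.
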