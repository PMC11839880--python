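# distfree

Distribution-free Bayesian inference for categorical, paired, and
independent-group data, with rank-based association measures and Monte Carlo
power analysis.

Behavioral and biomedical data are often messy: skewed, heavy-tailed,
outlier-prone, or only ordinal.  Classical nonparametric procedures (sign
test, McNemar, Wilcoxon signed-rank, Mann–Whitney U, Kendall correlation)
handle this by using only categorical or rank information, but as frequentist
tests they cannot attach probabilities to hypotheses.  `distfree` provides
the Bayesian counterparts: every procedure yields a posterior distribution
for an interpretable population parameter, together with interval estimates
and Bayes factors.

## The models

**Bernoulli-type data.**  Binary counts (n₁, n₂) with a Beta(a₀, b₀) prior on
the category-1 rate φ give the conjugate posterior Beta(a₀+n₁, b₀+n₂).  This
covers the binomial analysis, the McNemar change test (φ_rb = population
switching rate among the change cases), the sign test (φ = proportion of
positive paired differences), and the median test (φ = proportion of
above-median observations from group E, tested against its base rate
n_E/(n_E+n_C)).  Interval Bayes factors are posterior-to-prior odds ratios
computed from incomplete-beta masses; point nulls use the Savage–Dickey
density ratio.

**Contrasts across K conditions.**  A contrast Δ = Σᵢ ψᵢ φᵢ (positive ψ
summing to +1, negative to −1) compares K independent binomial conditions.
E(Δ) and V(Δ) are closed-form; P(Δ > 0), equal-tail intervals, and BF₁₀ come
from Monte Carlo sampling of the K beta posteriors.

**Rank statistics.**  For paired data the Wilcoxon T⁺ statistic estimates the
sign-bias parameter φ_w; for independent groups the Mann–Whitney U_E
estimates the stochastic-dominance parameter Ω_E = lim U_E/(U_E+U_C).  With
small samples the posterior is computed on a 200-point discrete grid
(.0025 to .9975 in steps of .005): at each candidate parameter value the
likelihood of the observed statistic is estimated by simulation (random sign
assignments to the ranks 1..n, or draws from exponential distributions
constructed to have the candidate Ω_E), then multiplied by the prior and
normalized.  With larger samples (n > 24 blocks, or harmonic mean of group
sizes > 19) a moment-matched beta approximation is used.  Contrasts over
K > 2 conditions reduce to the two-sample machinery by weighted composition
(paired) or group pooling (independent).

**Association.**  Kendall τ_A = (n_c − n_d)/(n_c + n_d) with exact tie
bookkeeping (n_c + n_d = N(N−1)/2 − T_X − T_Y + T_XY), linked to the
concordance proportion φ_c by τ_A = 2φ_c − 1, giving φ_c conjugate beta
inference.  Goodness-of-fit comparisons of scientific models penalize the
concordant count for m free parameters: n_c* = n_c − Nm + m(m+1)/2.
Goodman–Kruskal gamma provides the same analysis directly on ordered
contingency tables (N_s and N_d equal the expanded-point n_c and n_d).

**Power.**  Simulators draw two-condition data from nine probability models
(normal, Weibull, Cauchy, lognormal, chi-squared, logistic, exponential,
Gumbel, Pareto) with a location shift δ and optional uniform block effects,
then compare the Bayesian rank-test detection rate (posterior probability ≥
`effect_crit`) against the one-sided classical t test at α = 1 − `effect_crit`,
across 11 sample sizes or 21 separations.

## Worked example

Eighteen students tied a knot after a stressful delay; 16 chose the first
method they had learned and 2 the second.  Is the first-method rate φ above
one half?

```python
from distfree import (UNIFORM, BernoulliCounts, HypothesisSpec,
                      bayes_factor, beta_descriptive, binomial_posterior)

post = binomial_posterior(BernoulliCounts(16, 2), UNIFORM)   # Beta(17, 3)
s = beta_descriptive(post)
bf = bayes_factor(post, UNIFORM, HypothesisSpec("interval", (0.0, 0.5)))
```

This prints (via the obvious f-strings):

```
posterior Beta(17, 3)
mean=0.8500 median=0.8617 mode=0.8889
95% equal-tail=(0.6686, 0.9662)
95% HDI=(0.6974, 0.9801)
P(H0)=0.000364  BF10=2743.963
```

The posterior mean response rate is .85, the null φ ≤ .5 retains a mass of
only .000364, and the Bayes factor of about 2744 is overwhelming evidence
for φ > .5.

A paired rank analysis works the same way.  Ten paired scores with one zero
difference give the signed-rank sums T⁺ = 32, T⁻ = 13 over n = 9 informative
blocks, and the small-sample grid posterior for the sign-bias parameter:

```python
from distfree import wilcoxon_stats, wilcoxon_small_posterior

st = wilcoxon_stats(y1, y2)                       # T+=32, T-=13, n=9
w = wilcoxon_small_posterior(st, samples=30000, seed=42, quiet=True)
```

```
T+=32 T-=13 n=9
P(phi_w>.5)=0.8533  95% interval=(0.3459, 0.9115)  BF10=5.82
```

A posterior probability of .85 that φ_w > .5 (BF₁₀ ≈ 5.8) is suggestive but
not decisive — nine blocks carry limited information.

Every analysis is also available from the shell, e.g.
`distfree binomial --n1 16 --n2 2` or
`distfree wilcoxon --y1 y1.csv --y2 y2.csv --seed 42`; subcommands emit a
JSON envelope and exit non-zero with a one-line diagnostic on invalid input.

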