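"""Beta-distribution descriptives, Bernoulli conjugate updating, and Bayes factors.

The beta family is the conjugate prior for Bernoulli-process data: a
Beta(a0, b0) prior combined with n1 category-1 and n2 category-2 observations
yields a Beta(a0 + n1, b0 + n2) posterior.  Every other analysis in this
package (McNemar, sign, median, concordance, contrasts, and the rank-statistic
approximations) reduces to, or builds on, this machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize
from scipy import stats as _st

__all__ = [
    "BetaParams",
    "BernoulliCounts",
    "BetaSummary",
    "HypothesisSpec",
    "BayesFactorResult",
    "UNIFORM",
    "beta_descriptive",
    "binomial_posterior",
    "bayes_factor",
]


@dataclass(frozen=True)
class BetaParams:
    """Shape pair (a, b) of a beta distribution, prior or posterior."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("beta shape parameters must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                f"beta shape parameters must be positive, got a={self.a}, b={self.b}"
            )

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    @property
    def mode(self) -> float | None:
        """Interior mode (a-1)/(a+b-2); None when the density peaks on a boundary."""
        if self.a > 1 and self.b > 1:
            return (self.a - 1.0) / (self.a + self.b - 2.0)
        return None

    def pdf(self, x):
        return _st.beta.pdf(x, self.a, self.b)

    def cdf(self, x):
        return _st.beta.cdf(x, self.a, self.b)

    def sf(self, x):
        return _st.beta.sf(x, self.a, self.b)

    def ppf(self, q):
        return _st.beta.ppf(q, self.a, self.b)

    def rvs(self, size, rng):
        return rng.beta(self.a, self.b, size)

    def updated(self, n1: int, n2: int) -> "BetaParams":
        """Conjugate update with n1/n2 category counts."""
        return binomial_posterior(BernoulliCounts(n1, n2), self)


UNIFORM = BetaParams(1.0, 1.0)


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or value != int(value):
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return value


@dataclass(frozen=True)
class BernoulliCounts:
    """Observed category counts of a Bernoulli process.

    The combinatorial constant of the binomial likelihood is irrelevant here:
    it cancels between numerator and denominator of Bayes' theorem, so only
    the counts matter.
    """

    n1: int
    n2: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "n1", _check_count(self.n1, "n1"))
        object.__setattr__(self, "n2", _check_count(self.n2, "n2"))


@dataclass(frozen=True)
class BetaSummary:
    """Point and interval descriptives of a beta distribution.

    ``mode`` and ``hdi_interval`` are None when undefined (boundary-mode
    shapes); ``hdi_interval`` is one-sided ([0, q] or [q, 1]) when exactly one
    shape parameter is <= 1 so the density is monotone.
    """

    mean: float
    median: float
    mode: float | None
    variance: float
    eqtail_interval: tuple[float, float]
    hdi_interval: tuple[float, float] | None
    prob_interval: float


def _hdi(params: BetaParams, prob: float) -> tuple[float, float] | None:
    a, b = params.a, params.b
    if a > 1 and b > 1:
        # Narrowest interval of mass `prob`: minimise width over the lower
        # tail mass; the width is unimodal in the lower tail mass for a
        # unimodal density.
        def width(lo_mass: float) -> float:
            return params.ppf(lo_mass + prob) - params.ppf(lo_mass)

        res = optimize.minimize_scalar(
            width, bounds=(0.0, 1.0 - prob), method="bounded",
            options={"xatol": 1e-10},
        )
        lo = float(params.ppf(res.x))
        hi = float(params.ppf(res.x + prob))
        return (lo, hi)
    if a <= 1 < b:
        return (0.0, float(params.ppf(prob)))
    if b <= 1 < a:
        return (float(params.ppf(1.0 - prob)), 1.0)
    # a <= 1 and b <= 1: flat, U-shaped, or doubly unbounded density; no
    # meaningful highest-density interval.
    return None


def beta_descriptive(params: BetaParams, prob_interval: float = 0.95) -> BetaSummary:
    """Mean, median, mode, variance, equal-tail interval, and HDI.

    The median is the inverse regularized incomplete beta at 0.5; the
    equal-tail interval places mass (1 - prob_interval)/2 in each tail.
    """
    if not 0.0 < prob_interval < 1.0:
        raise ValueError("prob_interval must be strictly between 0 and 1")
    tail = (1.0 - prob_interval) / 2.0
    return BetaSummary(
        mean=params.mean,
        median=float(params.ppf(0.5)),
        mode=params.mode,
        variance=params.variance,
        eqtail_interval=(float(params.ppf(tail)), float(params.ppf(1.0 - tail))),
        hdi_interval=_hdi(params, prob_interval),
        prob_interval=prob_interval,
    )


def binomial_posterior(counts: BernoulliCounts, prior: BetaParams = UNIFORM) -> BetaParams:
    """Conjugate posterior Beta(a0 + n1, b0 + n2)."""
    return BetaParams(prior.a + counts.n1, prior.b + counts.n2)


@dataclass(frozen=True)
class HypothesisSpec:
    """Null hypothesis for a Bayes-factor test of a beta-distributed proportion.

    method="interval": H0 is a closed sub-interval [L, U] of [0, 1] with L < U.
    method="point": H0 is a single value in (0, 1); tested via the
    Savage-Dickey density ratio.
    """

    method: str
    h0: tuple[float, float] | float

    def __post_init__(self) -> None:
        if self.method == "interval":
            try:
                lo, hi = self.h0  # type: ignore[misc]
            except TypeError:
                raise ValueError(
                    "interval method requires H0 = (lower, upper)"
                ) from None
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"absurd interval H0=({lo}, {hi})")
            object.__setattr__(self, "h0", (float(lo), float(hi)))
        elif self.method == "point":
            try:
                point = float(self.h0)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValueError("point method requires a scalar H0") from None
            if not 0.0 < point < 1.0:
                raise ValueError("point H0 must lie strictly inside (0, 1)")
            object.__setattr__(self, "h0", point)
        else:
            raise ValueError(f"method must be 'interval' or 'point', got {self.method!r}")


@dataclass(frozen=True)
class BayesFactorResult:
    """BF10/BF01 with the prior and posterior hypothesis probabilities.

    For the point method the *_h0/*_h1 fields carry the prior and posterior
    densities at the null point rather than probabilities (a point null has
    zero probability under a continuous prior).
    """

    bf10: float
    bf01: float
    prior_h0: float
    prior_h1: float
    post_h0: float
    post_h1: float
    method: str


def _odds(p1: float, p0: float) -> float:
    if p0 == 0.0:
        return math.inf
    return p1 / p0


def bayes_factor(
    posterior: BetaParams, prior: BetaParams, hyp: HypothesisSpec
) -> BayesFactorResult:
    """Bayes factor for H1 against H0 on a beta prior/posterior pair.

    Interval method: BF10 is the posterior odds of H1 over H0 divided by the
    prior odds, with the hypothesis masses computed from the regularized
    incomplete beta.  Point method: Savage-Dickey ratio, BF01 = posterior
    density over prior density at the null point.

    Underflow of a hypothesis mass to exactly 0 is reported as an infinite
    Bayes factor (and 0 for its reciprocal).
    """
    if hyp.method == "interval":
        lo, hi = hyp.h0  # type: ignore[misc]
        prior_h0 = float(prior.cdf(hi) - prior.cdf(lo))
        post_h0 = float(posterior.cdf(hi) - posterior.cdf(lo))
        prior_h1 = 1.0 - prior_h0
        post_h1 = 1.0 - post_h0
        if prior_h0 == 0.0 or prior_h1 == 0.0:
            raise ValueError("prior assigns zero mass to one hypothesis; BF undefined")
        prior_odds = prior_h1 / prior_h0
        post_odds = _odds(post_h1, post_h0)
        bf10 = post_odds / prior_odds if math.isfinite(post_odds) else math.inf
        bf01 = 0.0 if bf10 == math.inf else (math.inf if bf10 == 0.0 else 1.0 / bf10)
        return BayesFactorResult(bf10, bf01, prior_h0, prior_h1, post_h0, post_h1, "interval")
    # point: Savage-Dickey density ratio
    point = hyp.h0  # type: ignore[assignment]
    d_prior = float(prior.pdf(point))
    d_post = float(posterior.pdf(point))
    if d_prior == 0.0:
        raise ValueError("prior density is zero at the null point; BF undefined")
    bf01 = d_post / d_prior
    bf10 = math.inf if bf01 == 0.0 else 1.0 / bf01
    return BayesFactorResult(bf10, bf01, d_prior, float("nan"), d_post, float("nan"), "point")
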