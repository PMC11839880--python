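"""Bayesian McNemar, sign, and median tests.

Each test reduces its input to two Bernoulli category counts and hands them
to the conjugate beta machinery: McNemar counts response switches in a
randomized-block 2x2 design, the sign test counts positive versus negative
paired differences, and the median test counts above-combined-median
observations per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beta_core import (
    UNIFORM,
    BetaParams,
    BetaSummary,
    BernoulliCounts,
    HypothesisSpec,
    bayes_factor,
    beta_descriptive,
    binomial_posterior,
)

__all__ = [
    "ChangeCounts",
    "McNemarResult",
    "SignTestResult",
    "MedianTestResult",
    "mcnemar",
    "sign_test",
    "median_test",
]


@dataclass(frozen=True)
class ChangeCounts:
    """Switch counts of a pre/post binary design: n_01 (0->1) and n_10 (1->0)."""

    n_01: int
    n_10: int

    def __post_init__(self) -> None:
        BernoulliCounts(self.n_01, self.n_10)  # reuse count validation


def _as_paired(y1, y2) -> tuple[np.ndarray, np.ndarray]:
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.ndim != 1 or y2.ndim != 1 or y1.size != y2.size:
        raise ValueError("Y1 and Y2 must be equal-length 1-D vectors")
    if y1.size < 1:
        raise ValueError("paired vectors must be non-empty")
    return y1, y2


@dataclass(frozen=True)
class McNemarResult:
    counts: ChangeCounts
    posterior: BetaParams
    summary: BetaSummary
    post_prob_gt_half: float
    bf10: float
    chi2_mcnemar: float


def mcnemar(
    counts: ChangeCounts,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> McNemarResult:
    """Bayesian change test for the switching rate phi_rb.

    phi_rb is oriented toward improvement (the 0->1 direction).  The
    no-continuity-correction chi-square (n_01-n_10)^2/(n_01+n_10) is included
    as a descriptive frequentist reference only.
    """
    post = binomial_posterior(BernoulliCounts(counts.n_01, counts.n_10), prior)
    total = counts.n_01 + counts.n_10
    chi2 = (counts.n_01 - counts.n_10) ** 2 / total if total > 0 else math.nan
    bf = bayes_factor(post, prior, HypothesisSpec("interval", (0.0, 0.5)))
    return McNemarResult(
        counts=counts,
        posterior=post,
        summary=beta_descriptive(post, prob_interval),
        post_prob_gt_half=bf.post_h1,
        bf10=bf.bf10,
        chi2_mcnemar=chi2,
    )


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    n_zero_dropped: int
    posterior: BetaParams
    summary: BetaSummary
    post_prob_gt_half: float
    bf10: float


def sign_test(
    y1,
    y2,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> SignTestResult:
    """Bayesian sign test on paired vectors.

    d_i = Y1_i - Y2_i; exact-zero differences are dropped (and counted), and
    phi is the population proportion of positive differences.  Zero detection
    is an exact floating-point comparison; values that differ only by noise
    below machine precision count as signed.
    """
    y1, y2 = _as_paired(y1, y2)
    d = y1 - y2
    n_zero = int(np.sum(d == 0.0))
    n_pos = int(np.sum(d > 0.0))
    n_neg = int(np.sum(d < 0.0))
    if n_pos + n_neg == 0:
        raise ValueError("no informative blocks: all paired differences are zero")
    post = binomial_posterior(BernoulliCounts(n_pos, n_neg), prior)
    bf = bayes_factor(post, prior, HypothesisSpec("interval", (0.0, 0.5)))
    return SignTestResult(
        n_pos=n_pos,
        n_neg=n_neg,
        n_zero_dropped=n_zero,
        posterior=post,
        summary=beta_descriptive(post, prob_interval),
        post_prob_gt_half=bf.post_h1,
        bf10=bf.bf10,
    )


@dataclass(frozen=True)
class MedianTestResult:
    combined_median: float
    above_e: int
    above_c: int
    n_e: int
    n_c: int
    base_rate_e: float
    posterior: BetaParams
    summary: BetaSummary
    post_prob_h1: float
    post_prob_h0: float
    bf10: float


def median_test(
    e,
    c,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> MedianTestResult:
    """Bayesian median test for two independent groups of possibly unequal size.

    Counts the observations *strictly above* the combined median in each
    group (scores at the median are never counted as above) and tests
    H0: phi <= nE/(nE+nC) against H1: phi > that base rate, where phi is the
    population proportion of above-median observations belonging to E.
    """
    e = np.asarray(e, dtype=float)
    c = np.asarray(c, dtype=float)
    if e.ndim != 1 or c.ndim != 1 or e.size < 1 or c.size < 1:
        raise ValueError("E and C must be non-empty 1-D vectors")
    pooled = np.concatenate([e, c])
    med = float(np.median(pooled))
    above_e = int(np.sum(e > med))
    above_c = int(np.sum(c > med))
    if above_e + above_c == 0:
        raise ValueError("no observations above the combined median (all values equal?)")
    base_rate = e.size / (e.size + c.size)
    post = binomial_posterior(BernoulliCounts(above_e, above_c), prior)
    bf = bayes_factor(post, prior, HypothesisSpec("interval", (0.0, base_rate)))
    return MedianTestResult(
        combined_median=med,
        above_e=above_e,
        above_c=above_c,
        n_e=int(e.size),
        n_c=int(c.size),
        base_rate_e=base_rate,
        posterior=post,
        summary=beta_descriptive(post, prob_interval),
        post_prob_h1=bf.post_h1,
        post_prob_h0=bf.post_h0,
        bf10=bf.bf10,
    )
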