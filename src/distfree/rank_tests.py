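"""Bayesian Wilcoxon signed-rank and Mann-Whitney posteriors.

Small samples: the posterior for the Wilcoxon sign-bias parameter phi_w, or
for the Mann-Whitney stochastic-dominance parameter Omega_E, is approximated
on a 200-point discrete grid (.0025, .0075, ..., .9975).  At each candidate
parameter value the likelihood of the observed rank statistic is estimated by
Monte Carlo: random sign assignments to the ranks 1..n for the Wilcoxon, or
random draws from a pair of exponential distributions constructed to have the
candidate Omega_E for the Mann-Whitney.  The likelihoods are multiplied by the
prior on the grid and normalized.

Large samples: the sampling distribution of the statistic given the parameter
is well approximated by a normal, so a grid posterior built from the normal
likelihood is moment-matched to a beta distribution.  The automatic cutovers
are n > 24 blocks (Wilcoxon) and a harmonic mean of the group sizes > 19
(Mann-Whitney).

For K > 2 conditions the same machinery applies to a contrast: paired designs
compose a weighted pair of variates (`composite_pair`); independent designs
pool the positive-side and negative-side groups (`pool_groups`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .beta_core import UNIFORM, BetaParams
from .beta_contrast import validate_weights

__all__ = [
    "GRID",
    "WilcoxonStats",
    "MannWhitneyStats",
    "DiscretePosterior",
    "RankPosterior",
    "wilcoxon_stats",
    "mann_whitney_stats",
    "wilcoxon_small_posterior",
    "wilcoxon_exact_posterior",
    "mann_whitney_small_posterior",
    "rank_large_posterior",
    "wilcoxon",
    "mann_whitney",
    "composite_pair",
    "pool_groups",
]

logger = logging.getLogger(__name__)

#: 200 candidate parameter values .0025, .0075, ..., .9975 (step .005).
GRID = 0.0025 + 0.005 * np.arange(200)

WILCOXON_SMALL_MAX_N = 24
MW_LARGE_HARMONIC_CUTOFF = 19.0


@dataclass(frozen=True)
class WilcoxonStats:
    """Signed-rank sums T+ and T- over the non-zero-difference blocks."""

    t_plus: float
    t_minus: float
    n_blocks: int
    n_zero_dropped: int = 0


@dataclass(frozen=True)
class MannWhitneyStats:
    """Cross-group dominance counts U_E and U_C (ties count toward neither)."""

    u_e: float
    u_c: float
    n_e: int
    n_c_size: int


def wilcoxon_stats(y1, y2) -> WilcoxonStats:
    """T+ and T- from paired vectors: rank |d| ascending with midranks for ties,
    dropping zero differences, and sum the ranks by sign of d."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.ndim != 1 or y1.shape != y2.shape:
        raise ValueError("Y1 and Y2 must be equal-length 1-D vectors")
    d = y1 - y2
    nz = d != 0.0
    n_zero = int(np.sum(~nz))
    d = d[nz]
    if d.size == 0:
        raise ValueError("no informative blocks: all paired differences are zero")
    ranks = _st.rankdata(np.abs(d))
    return WilcoxonStats(
        t_plus=float(ranks[d > 0].sum()),
        t_minus=float(ranks[d < 0].sum()),
        n_blocks=int(d.size),
        n_zero_dropped=n_zero,
    )


def mann_whitney_stats(e, c) -> MannWhitneyStats:
    """U_E and U_C by exhaustive strict pairwise comparison of the two groups."""
    e = np.asarray(e, dtype=float)
    c = np.asarray(c, dtype=float)
    if e.ndim != 1 or c.ndim != 1 or e.size == 0 or c.size == 0:
        raise ValueError("E and C must be non-empty 1-D vectors")
    diff = e[:, None] - c[None, :]
    return MannWhitneyStats(
        u_e=float(np.sum(diff > 0)),
        u_c=float(np.sum(diff < 0)),
        n_e=int(e.size),
        n_c_size=int(c.size),
    )


@dataclass(frozen=True)
class DiscretePosterior:
    """Probability distribution over the 200-point parameter grid."""

    grid: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != self.grid.shape or np.any(probs < 0):
            raise ValueError("probs must be non-negative and match the grid")
        total = probs.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError("grid probabilities must sum to 1")

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.probs))

    @property
    def variance(self) -> float:
        return float(np.sum(self.grid**2 * self.probs) - self.mean**2)

    def prob_greater(self, x: float) -> float:
        return float(self.probs[self.grid > x].sum())

    def quantile(self, q) -> np.ndarray:
        """Quantiles by linear interpolation of the step CDF between grid points."""
        cdf = np.cumsum(self.probs)
        return np.interp(q, cdf, self.grid)


@dataclass(frozen=True)
class RankPosterior:
    """Posterior for phi_w or Omega_E with H1: parameter > .5 summaries."""

    parameter: str  # "phi_w" or "omega_E"
    method_used: str  # "small" | "small-exact" | "large"
    discrete: DiscretePosterior | None
    beta_approx: BetaParams | None
    posterior_mean: float
    post_prob_gt_half: float
    prior_prob_gt_half: float
    eqtail_interval: tuple[float, float]
    prob_interval: float
    bf10: float
    prior: BetaParams
    samples_per_grid_point: int | None = None
    seed: int | None = None


def _grid_prior(prior: BetaParams) -> np.ndarray:
    # Beta density at the grid points, grid-normalized (not bin-integrated);
    # the difference is O(step^2).
    w = prior.pdf(GRID)
    return w / w.sum()


def _bf10_from_masses(post_h1: float, prior_h1: float) -> float:
    post_h0 = 1.0 - post_h1
    prior_h0 = 1.0 - prior_h1
    if post_h0 <= 0.0:
        return math.inf
    if post_h1 <= 0.0:
        return 0.0
    return (post_h1 / post_h0) / (prior_h1 / prior_h0)


def _discrete_rank_posterior(
    likelihood: np.ndarray,
    prior: BetaParams,
    parameter: str,
    method_used: str,
    prob_interval: float,
    samples: int | None,
    seed: int | None,
) -> RankPosterior:
    prior_w = _grid_prior(prior)
    numer = likelihood * prior_w
    total = numer.sum()
    if total <= 0.0:
        raise ValueError(
            "observed statistic was never reproduced at any grid value "
            "(zero likelihood everywhere); try method='large'"
        )
    disc = DiscretePosterior(GRID, numer / total)
    post_h1 = disc.prob_greater(0.5)
    prior_h1 = float(prior_w[GRID > 0.5].sum())
    tail = (1.0 - prob_interval) / 2.0
    lo, hi = disc.quantile([tail, 1.0 - tail])
    return RankPosterior(
        parameter=parameter,
        method_used=method_used,
        discrete=disc,
        beta_approx=None,
        posterior_mean=disc.mean,
        post_prob_gt_half=post_h1,
        prior_prob_gt_half=prior_h1,
        eqtail_interval=(float(lo), float(hi)),
        prob_interval=prob_interval,
        bf10=_bf10_from_masses(post_h1, prior_h1),
        prior=prior,
        samples_per_grid_point=samples,
        seed=seed,
    )


def _progress(i: int, total: int, quiet: bool, label: str) -> None:
    if not quiet and i % 40 == 0:
        logger.info("%s: %d%% complete", label, round(100 * i / total))


def wilcoxon_small_posterior(
    stats: WilcoxonStats,
    prior: BetaParams = UNIFORM,
    samples: int = 30_000,
    seed: int | None = None,
    prob_interval: float = 0.95,
    quiet: bool = False,
) -> RankPosterior:
    """Discrete Monte Carlo posterior for the sign-bias parameter phi_w.

    At each grid value phi the ranks 1..n are independently signed positive
    with probability phi; the likelihood is the proportion of sampled T+
    values matching the observed T+ (rounded to the nearest integer, since
    midranks from tied |d| can make the observed value non-integer while the
    sampler's support is integer).
    """
    n = stats.n_blocks
    t_obs = int(round(stats.t_plus))
    ranks = np.arange(1, n + 1, dtype=float)
    rng = np.random.default_rng(seed)
    lik = np.empty(GRID.size)
    for i, phi in enumerate(GRID):
        t_samp = (rng.random((samples, n)) < phi) @ ranks
        lik[i] = np.mean(np.rint(t_samp).astype(int) == t_obs)
        _progress(i + 1, GRID.size, quiet, "wilcoxon small-n")
    return _discrete_rank_posterior(
        lik, prior, "phi_w", "small", prob_interval, samples, seed
    )


def _wilcoxon_exact_likelihood(n: int, t_obs: int) -> np.ndarray:
    """Exact P(T+ = t_obs | phi) on the grid via dynamic programming.

    Expands the probability generating function prod_r ((1-phi) + phi z^r)
    over the ranks r = 1..n; this is the samples -> infinity limit of the
    Monte Carlo sampler used by `wilcoxon_small_posterior`.
    """
    t_max = n * (n + 1) // 2
    if not 0 <= t_obs <= t_max:
        return np.zeros(GRID.size)
    p = GRID[:, None]
    dist = np.zeros((GRID.size, t_max + 1))
    dist[:, 0] = 1.0
    for r in range(1, n + 1):
        new = (1.0 - p) * dist
        new[:, r:] += p * dist[:, :-r]
        dist = new
    return dist[:, t_obs]


def wilcoxon_exact_posterior(
    stats: WilcoxonStats,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> RankPosterior:
    """Small-n grid posterior with the likelihood computed exactly.

    Identical target distribution to `wilcoxon_small_posterior` but with the
    Monte Carlo likelihood replaced by its exact dynamic-programming value;
    deterministic and fast, used by the power simulator.
    """
    lik = _wilcoxon_exact_likelihood(stats.n_blocks, int(round(stats.t_plus)))
    return _discrete_rank_posterior(
        lik, prior, "phi_w", "small-exact", prob_interval, None, None
    )


def _mw_sample_ue(omega: float, n_e: int, n_c: int, samples: int, rng) -> np.ndarray:
    """Sampled U_E under the exponential construction with P(X_C < X_E) = omega."""
    # Exponential rates (1-omega) for E and omega for C give
    # P(C < E) = rate_C / (rate_C + rate_E) = omega.
    u = np.empty(samples)
    # chunk to bound the (chunk, n_e, n_c) comparison tensor
    chunk = max(1, int(4_000_000 / max(n_e * n_c, 1)))
    for start in range(0, samples, chunk):
        m = min(chunk, samples - start)
        e = rng.exponential(1.0 / (1.0 - omega), (m, n_e))
        c = rng.exponential(1.0 / omega, (m, n_c))
        u[start : start + m] = np.sum(e[:, :, None] > c[:, None, :], axis=(1, 2))
    return u


def mann_whitney_small_posterior(
    stats: MannWhitneyStats,
    prior: BetaParams = UNIFORM,
    samples: int = 30_000,
    seed: int | None = None,
    prob_interval: float = 0.95,
    quiet: bool = False,
) -> RankPosterior:
    """Discrete Monte Carlo posterior for the dominance parameter Omega_E.

    At each grid value Omega, n_e values are drawn from an exponential with
    rate (1 - Omega) and n_c from an exponential with rate Omega, so that
    P(X_C < X_E) = Omega; the likelihood is the proportion of sampled U_E
    matching the observed U_E (rounded to the nearest integer).
    """
    u_obs = int(round(stats.u_e))
    rng = np.random.default_rng(seed)
    lik = np.empty(GRID.size)
    for i, omega in enumerate(GRID):
        u = _mw_sample_ue(omega, stats.n_e, stats.n_c_size, samples, rng)
        lik[i] = np.mean(u.astype(int) == u_obs)
        _progress(i + 1, GRID.size, quiet, "mann-whitney small-n")
    return _discrete_rank_posterior(
        lik, prior, "omega_E", "small", prob_interval, samples, seed
    )


# Pilot-calibrated U_E sampling variances at Omega=.5, keyed by (n_e, n_c).
_MW_VAR_CACHE: dict[tuple[int, int, int], float] = {}


def _mw_pilot_variance(n_e: int, n_c: int, pilot_samples: int = 10_000) -> float:
    key = (n_e, n_c, pilot_samples)
    if key not in _MW_VAR_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([7919, n_e, n_c]))
        u = _mw_sample_ue(0.5, n_e, n_c, pilot_samples, rng)
        _MW_VAR_CACHE[key] = float(u.var(ddof=1))
    return _MW_VAR_CACHE[key]


def _beta_from_moments(mean: float, var: float) -> BetaParams:
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        raise ValueError("grid posterior variance too large for a beta fit")
    return BetaParams(mean * nu, (1.0 - mean) * nu)


def rank_large_posterior(
    stats: WilcoxonStats | MannWhitneyStats,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> RankPosterior:
    """Large-sample beta approximation for phi_w or Omega_E.

    A normal approximation to the sampling distribution of the statistic given
    the parameter is evaluated on the 200-point grid, multiplied by the prior,
    and the resulting grid posterior is moment-matched to a beta distribution.
    Wilcoxon: T+ ~ N(phi n(n+1)/2, phi(1-phi) n(n+1)(2n+1)/6).  Mann-Whitney:
    U_E ~ N(Omega n_e n_c, v), with v calibrated once per group-size pair by a
    pilot run of the exponential-construction sampler at Omega=.5 and scaled
    by Omega(1-Omega)/.25.
    """
    if isinstance(stats, WilcoxonStats):
        parameter = "phi_w"
        n = stats.n_blocks
        obs = stats.t_plus
        mu = GRID * n * (n + 1) / 2.0
        var = GRID * (1.0 - GRID) * n * (n + 1) * (2 * n + 1) / 6.0
    elif isinstance(stats, MannWhitneyStats):
        parameter = "omega_E"
        obs = stats.u_e
        mu = GRID * stats.n_e * stats.n_c_size
        v0 = _mw_pilot_variance(stats.n_e, stats.n_c_size)
        var = v0 * GRID * (1.0 - GRID) / 0.25
    else:
        raise TypeError("stats must be WilcoxonStats or MannWhitneyStats")

    lik = np.exp(-0.5 * (obs - mu) ** 2 / var) / np.sqrt(var)
    prior_w = _grid_prior(prior)
    probs = lik * prior_w
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate large-sample likelihood")
    probs /= total
    mean = float(np.sum(GRID * probs))
    var_post = float(np.sum(GRID**2 * probs) - mean**2)
    fit = _beta_from_moments(mean, var_post)

    post_h1 = float(fit.sf(0.5))
    prior_h1 = float(prior.sf(0.5))
    tail = (1.0 - prob_interval) / 2.0
    return RankPosterior(
        parameter=parameter,
        method_used="large",
        discrete=None,
        beta_approx=fit,
        posterior_mean=fit.mean,
        post_prob_gt_half=post_h1,
        prior_prob_gt_half=prior_h1,
        eqtail_interval=(float(fit.ppf(tail)), float(fit.ppf(1.0 - tail))),
        prob_interval=prob_interval,
        bf10=_bf10_from_masses(post_h1, prior_h1),
        prior=prior,
    )


def wilcoxon(
    y1,
    y2,
    prior: BetaParams = UNIFORM,
    method: str | None = None,
    samples: int = 30_000,
    seed: int | None = None,
    prob_interval: float = 0.95,
    quiet: bool = False,
) -> RankPosterior:
    """Bayesian Wilcoxon signed-rank analysis of paired vectors.

    Auto-selects the small-n discrete method for n <= 24 blocks and the
    large-n beta approximation otherwise; override with method="small" or
    method="large".
    """
    stats = wilcoxon_stats(y1, y2)
    if method is None:
        method = "small" if stats.n_blocks <= WILCOXON_SMALL_MAX_N else "large"
    if method == "small":
        return wilcoxon_small_posterior(stats, prior, samples, seed, prob_interval, quiet)
    if method == "large":
        return rank_large_posterior(stats, prior, prob_interval)
    raise ValueError("method must be 'small', 'large', or None")


def mann_whitney(
    e,
    c,
    prior: BetaParams = UNIFORM,
    method: str | None = None,
    samples: int = 30_000,
    seed: int | None = None,
    prob_interval: float = 0.95,
    quiet: bool = False,
) -> RankPosterior:
    """Bayesian Mann-Whitney analysis of two independent groups.

    Auto-selects the large-sample beta approximation when the harmonic mean
    of the group sizes exceeds 19, the small-sample discrete method otherwise.
    """
    stats = mann_whitney_stats(e, c)
    if method is None:
        harmonic = 2.0 / (1.0 / stats.n_e + 1.0 / stats.n_c_size)
        method = "large" if harmonic > MW_LARGE_HARMONIC_CUTOFF else "small"
    if method == "small":
        return mann_whitney_small_posterior(stats, prior, samples, seed, prob_interval, quiet)
    if method == "large":
        return rank_large_posterior(stats, prior, prob_interval)
    raise ValueError("method must be 'small', 'large', or None")


def composite_pair(data_matrix, weights) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a blocks-by-K matrix into a weighted pair for a contrast.

    Y1 is the weighted sum of the positive-coefficient columns, Y2 the
    weighted sum (by |psi|) of the negative-coefficient columns, so a Wilcoxon
    analysis of (Y1, Y2) tests the contrast in a paired design.
    """
    data = np.asarray(data_matrix, dtype=float)
    w = validate_weights(np.asarray(weights))
    if data.ndim != 2 or data.shape[1] != w.size:
        raise ValueError("data matrix must be blocks x K with K matching the weights")
    y1 = data[:, w > 0] @ w[w > 0]
    y2 = data[:, w < 0] @ (-w[w < 0])
    return y1, y2


def pool_groups(columns, weights) -> tuple[np.ndarray, np.ndarray]:
    """Pool independent-group columns by contrast-weight sign.

    E concatenates the positive-side columns, C the negative-side ones, so a
    Mann-Whitney analysis of (E, C) tests the contrast for independent groups.
    """
    w = np.asarray(weights, dtype=float)
    if len(columns) != w.size:
        raise ValueError("one weight per column is required")
    pos = [np.asarray(col, dtype=float) for col, wi in zip(columns, w) if wi > 0]
    neg = [np.asarray(col, dtype=float) for col, wi in zip(columns, w) if wi < 0]
    if not pos or not neg:
        raise ValueError("need at least one positive-side and one negative-side column")
    return np.concatenate(pos), np.concatenate(neg)
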