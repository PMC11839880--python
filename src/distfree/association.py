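"""Rank-based bivariate association: Kendall tau-A, the concordance
proportion phi_c, goodness-of-fit adjustment, and Goodman-Kruskal gamma.

Every unordered pair of bivariate points is concordant (both coordinate
differences strictly share a sign), discordant (strictly opposite), or lost
to a tie.  tau_A = (n_c - n_d)/(n_c + n_d) with the denominator corrected for
ties through the lost-comparison totals T_X, T_Y, T_XY, and maps linearly to
the concordance proportion via tau_A = 2 phi_c - 1.  Since each comparable
pair is a Bernoulli trial, phi_c gets conjugate beta inference.

For goodness-of-fit use, (x, y) are the observed values and a model's fitted
values; each of m free-fitting parameters forfeits one condition's worth of
comparisons, giving the adjusted concordant count
n_c* = n_c - N m + m(m+1)/2 (discordant count unadjusted).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .beta_core import (
    UNIFORM,
    BetaParams,
    BetaSummary,
    beta_descriptive,
)

__all__ = [
    "PairCounts",
    "AdjustedConcordance",
    "ConcordanceResult",
    "GammaResult",
    "concordance_counts",
    "tau_a",
    "concordance_posterior",
    "concordance",
    "gamma_table",
]


@dataclass(frozen=True)
class PairCounts:
    """Concordant/discordant counts and tie-loss totals over N(N-1)/2 pairs."""

    n_c: int
    n_d: int
    t_x: int
    t_y: int
    t_xy: int
    n_points: int

    def __post_init__(self) -> None:
        for name in ("n_c", "n_d", "t_x", "t_y", "t_xy", "n_points"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        n = self.n_points
        expected = n * (n - 1) // 2 - self.t_x - self.t_y + self.t_xy
        if self.n_c + self.n_d != expected:
            raise ValueError(
                "inconsistent pair counts: n_c + n_d must equal "
                "N(N-1)/2 - T_X - T_Y + T_XY "
                f"({self.n_c + self.n_d} != {expected})"
            )


def _tie_total(values) -> int:
    return sum(t * (t - 1) // 2 for t in Counter(values).values())


def concordance_counts(x, y) -> PairCounts:
    """Exhaustive pairwise comparison of two equal-length vectors.

    Ranks never need to be materialized: the sign of a raw-value difference
    equals the sign of the rank difference, so the comparisons operate on the
    raw values directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two points")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    upper = np.triu_indices(n, k=1)
    prod = sx[upper] * sy[upper]
    return PairCounts(
        n_c=int(np.sum(prod > 0)),
        n_d=int(np.sum(prod < 0)),
        t_x=_tie_total(x.tolist()),
        t_y=_tie_total(y.tolist()),
        t_xy=_tie_total(list(zip(x.tolist(), y.tolist()))),
        n_points=n,
    )


def tau_a(counts: PairCounts) -> float:
    """Kendall tau-A = (n_c - n_d)/(n_c + n_d), exact under ties."""
    total = counts.n_c + counts.n_d
    if total == 0:
        raise ValueError("no comparable pairs: all pairs are multiply tied")
    return (counts.n_c - counts.n_d) / total


@dataclass(frozen=True)
class AdjustedConcordance:
    m: int
    n_c_star: int
    sample_phi_c_star: float
    posterior: BetaParams
    summary: BetaSummary


@dataclass(frozen=True)
class ConcordanceResult:
    counts: PairCounts
    tau_a: float
    sample_phi_c: float
    posterior: BetaParams
    summary: BetaSummary
    tau_eqtail_interval: tuple[float, float]
    adjusted: AdjustedConcordance | None


def concordance_posterior(
    counts: PairCounts,
    prior: BetaParams = UNIFORM,
    m: int = 0,
    prob_interval: float = 0.95,
) -> ConcordanceResult:
    """Beta posterior for phi_c, optionally penalized for m fitting parameters.

    tau_A intervals are the monotone transform 2q - 1 of the phi_c quantiles,
    not a re-estimation.
    """
    if m != int(m) or m < 0:
        raise ValueError("m must be a non-negative integer")
    m = int(m)
    post = BetaParams(prior.a + counts.n_c, prior.b + counts.n_d)
    summary = beta_descriptive(post, prob_interval)
    lo, hi = summary.eqtail_interval
    adjusted = None
    if m > 0:
        n_c_star = counts.n_c - counts.n_points * m + m * (m + 1) // 2
        if n_c_star <= 0:
            raise ValueError(
                "over-parameterized model: adjusted concordant count "
                f"n_c* = {n_c_star} is not positive"
            )
        post_star = BetaParams(prior.a + n_c_star, prior.b + counts.n_d)
        adjusted = AdjustedConcordance(
            m=m,
            n_c_star=n_c_star,
            sample_phi_c_star=n_c_star / (n_c_star + counts.n_d),
            posterior=post_star,
            summary=beta_descriptive(post_star, prob_interval),
        )
    return ConcordanceResult(
        counts=counts,
        tau_a=tau_a(counts),
        sample_phi_c=counts.n_c / (counts.n_c + counts.n_d),
        posterior=post,
        summary=summary,
        tau_eqtail_interval=(2.0 * lo - 1.0, 2.0 * hi - 1.0),
        adjusted=adjusted,
    )


def concordance(
    x,
    y,
    prior: BetaParams = UNIFORM,
    m: int = 0,
    prob_interval: float = 0.95,
) -> ConcordanceResult:
    """Count the pairs of (x, y) and run the phi_c posterior in one call."""
    return concordance_posterior(concordance_counts(x, y), prior, m, prob_interval)


@dataclass(frozen=True)
class GammaResult:
    n_s: int
    n_d: int
    g: float
    posterior: BetaParams
    summary: BetaSummary


def _validate_table(table) -> np.ndarray:
    cells = np.asarray(table)
    if cells.ndim != 2 or cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(cells < 0) or np.any(cells != cells.astype(int)):
        raise ValueError("table entries must be non-negative integers")
    if cells.sum() == 0:
        raise ValueError("table must contain at least one observation")
    return cells.astype(int)


def gamma_table(
    table,
    prior: BetaParams = UNIFORM,
    prob_interval: float = 0.95,
) -> GammaResult:
    """Goodman-Kruskal gamma on an ordered R x C contingency table.

    N_s pairs each cell with the cells strictly below and to the right, N_d
    with those strictly below and to the left; G = (N_s - N_d)/(N_s + N_d).
    N_s and N_d equal the n_c and n_d of the expanded point set, so phi_c
    gets the same conjugate beta posterior.
    """
    cells = _validate_table(table)
    r, c = cells.shape
    n_s = 0
    n_d = 0
    for i in range(r - 1):
        lower = cells[i + 1 :]
        for j in range(c):
            if j < c - 1:
                n_s += cells[i, j] * lower[:, j + 1 :].sum()
            if j > 0:
                n_d += cells[i, j] * lower[:, :j].sum()
    if n_s + n_d == 0:
        raise ValueError("no comparable pairs: all mass in one row or one column")
    post = BetaParams(prior.a + n_s, prior.b + n_d)
    return GammaResult(
        n_s=int(n_s),
        n_d=int(n_d),
        g=(n_s - n_d) / (n_s + n_d),
        posterior=post,
        summary=beta_descriptive(post, prob_interval),
    )
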