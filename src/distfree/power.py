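"""Monte Carlo power comparison: Bayesian rank tests versus the t test.

Data for two conditions are simulated under one of nine probability models
with a pure location shift `delta` applied to the second (experimental)
condition.  Each simulated data set is analysed twice: with the Bayesian
distribution-free posterior (Wilcoxon phi_w for paired designs, Mann-Whitney
Omega_E for independent designs) and with the classical t test (paired, or
pooled-variance two-sample).  A replication counts as a Bayesian detection
when the posterior probability of the one-sided alternative reaches
`effect_crit`, and as a t detection when the one-sided upper-tail p-value is
below 1 - effect_crit (the matched alpha).

Block effects emulate between-subject variability: a Uniform(0, block_max)
draw per block is added to both members of a pair (so pairing removes it
exactly), or independently to every observation in the independent design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .beta_core import UNIFORM, BetaParams
from . import rank_tests as rt

__all__ = ["MODELS", "SimSpec", "SimOutcome", "SimResult", "PowerTable",
           "sim_data", "bayes_vs_t_power", "power_curve"]

logger = logging.getLogger(__name__)

# Per-model samplers; `shape` is the single per-condition model parameter.
# Fixed auxiliary parameterizations: unit scale (weibull), meanlog 0
# (lognormal), location 0 (cauchy, logistic, gumbel), minimum 1 (pareto),
# shape = rate (exponential), shape = sd (normal), shape = df (chisquare).
MODELS = {
    "normal": lambda rng, n, shape: rng.normal(0.0, shape, n),
    "weibull": lambda rng, n, shape: rng.weibull(shape, n),
    "cauchy": lambda rng, n, shape: shape * rng.standard_cauchy(n),
    "lognormal": lambda rng, n, shape: rng.lognormal(0.0, shape, n),
    "chisquare": lambda rng, n, shape: rng.chisquare(shape, n),
    "logistic": lambda rng, n, shape: rng.logistic(0.0, shape, n),
    "exponential": lambda rng, n, shape: rng.exponential(1.0 / shape, n),
    "gumbel": lambda rng, n, shape: rng.gumbel(0.0, shape, n),
    "pareto": lambda rng, n, shape: 1.0 + rng.pareto(shape, n),
}

_DESIGNS = ("paired", "independent")


@dataclass(frozen=True)
class SimSpec:
    """One simulated two-condition data set: model, design, and separation."""

    model: str
    design: str
    n: int
    delta: float = 0.0
    shape1: float = 1.0
    shape2: float = 1.0
    block_max: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {sorted(MODELS)}"
            )
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}, got {self.design!r}")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.n < 2:
            raise ValueError("per-condition sample size n must be >= 2")
        if self.block_max < 0:
            raise ValueError("block_max must be non-negative")


@dataclass(frozen=True)
class SimOutcome:
    bayes_post_prob: float
    t_pvalue: float


@dataclass(frozen=True)
class SimResult:
    sample_c: np.ndarray = field(repr=False)
    sample_e: np.ndarray = field(repr=False)
    outcome: SimOutcome


def _one_sided_t(e: np.ndarray, c: np.ndarray, paired: bool) -> float:
    """Upper-tail p-value of the classical t test for the E > C direction."""
    if paired:
        d = e - c
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0.0:
            return 0.0 if d.mean() > 0 else 1.0
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        ne, nc = e.size, c.size
        sp2 = ((ne - 1) * e.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / (ne + nc - 2)
        if sp2 == 0.0:
            return 0.0 if e.mean() > c.mean() else 1.0
        t = (e.mean() - c.mean()) / np.sqrt(sp2 * (1.0 / ne + 1.0 / nc))
        df = ne + nc - 2
    return float(_st.t.sf(t, df))


def _bayes_prob(e: np.ndarray, c: np.ndarray, paired: bool, prior: BetaParams,
                small_samples: int, rng) -> float:
    if paired:
        d = e - c
        if np.all(d == 0.0):
            return 0.5
        stats = rt.wilcoxon_stats(e, c)
        if stats.n_blocks <= rt.WILCOXON_SMALL_MAX_N:
            # exact evaluation of the small-n grid likelihood (no MC error)
            post = rt.wilcoxon_exact_posterior(stats, prior)
        else:
            post = rt.rank_large_posterior(stats, prior)
        return post.post_prob_gt_half
    stats = rt.mann_whitney_stats(e, c)
    harmonic = 2.0 / (1.0 / stats.n_e + 1.0 / stats.n_c_size)
    if harmonic > rt.MW_LARGE_HARMONIC_CUTOFF:
        post = rt.rank_large_posterior(stats, prior)
    else:
        post = rt.mann_whitney_small_posterior(
            stats, prior, samples=small_samples,
            seed=int(rng.integers(2**31)), quiet=True,
        )
    return post.post_prob_gt_half


def sim_data(
    spec: SimSpec,
    prior: BetaParams = UNIFORM,
    small_samples: int = 30_000,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate one data set under `spec` and analyse it both ways.

    Condition C is drawn from the model with shape1; condition E from the
    model with shape2, shifted by +delta.  Returns the samples together with
    the Bayesian posterior probability of the alternative and the one-sided
    t-test p-value.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sampler = MODELS[spec.model]
    c = sampler(rng, spec.n, spec.shape1)
    e = sampler(rng, spec.n, spec.shape2) + spec.delta
    if spec.block_max > 0:
        if spec.design == "paired":
            block = rng.uniform(0.0, spec.block_max, spec.n)
            c = c + block
            e = e + block
        else:
            c = c + rng.uniform(0.0, spec.block_max, spec.n)
            e = e + rng.uniform(0.0, spec.block_max, spec.n)
    paired = spec.design == "paired"
    outcome = SimOutcome(
        bayes_post_prob=_bayes_prob(e, c, paired, prior, small_samples, rng),
        t_pvalue=_one_sided_t(e, c, paired),
    )
    return SimResult(sample_c=c, sample_e=e, outcome=outcome)


@dataclass(frozen=True)
class PowerTable:
    """Bayesian and t power along a sample-size or separation axis."""

    axis_name: str  # "n" or "delta"
    axis: np.ndarray
    bayes_power: np.ndarray
    t_power: np.ndarray
    samples: int
    effect_crit: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.axis_name: self.axis, "bayes_power": self.bayes_power,
             "t_power": self.t_power}
        )


def _power_cells(
    cells: list[SimSpec],
    axis_name: str,
    axis: np.ndarray,
    prior: BetaParams,
    effect_crit: float,
    samples: int,
    seed: int | None,
    quiet: bool,
) -> PowerTable:
    alpha = 1.0 - effect_crit
    children = np.random.SeedSequence(seed).spawn(len(cells))
    bayes_power = np.empty(len(cells))
    t_power = np.empty(len(cells))
    for i, (cell, child) in enumerate(zip(cells, children)):
        rng = np.random.default_rng(child)
        bayes_hits = 0
        t_hits = 0
        for _ in range(samples):
            out = sim_data(cell, prior=prior, rng=rng).outcome
            bayes_hits += out.bayes_post_prob >= effect_crit
            t_hits += out.t_pvalue < alpha
        bayes_power[i] = bayes_hits / samples
        t_power[i] = t_hits / samples
        if not quiet:
            logger.info(
                "power cell %d/%d (%s=%g): bayes=%.3f t=%.3f",
                i + 1, len(cells), axis_name, axis[i], bayes_power[i], t_power[i],
            )
    return PowerTable(axis_name, axis, bayes_power, t_power, samples, effect_crit)


def bayes_vs_t_power(
    delta: float,
    model: str,
    design: str,
    n_min: int = 20,
    prior: BetaParams = UNIFORM,
    effect_crit: float = 0.95,
    shape1: float = 1.0,
    shape2: float = 1.0,
    samples: int = 1000,
    block_max: float = 0.0,
    seed: int | None = None,
    quiet: bool = False,
) -> PowerTable:
    """Power at 11 per-condition sample sizes n_min, n_min+5, ..., n_min+50."""
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    ns = np.arange(n_min, n_min + 55, 5)
    cells = [
        SimSpec(model=model, design=design, n=int(n), delta=delta,
                shape1=shape1, shape2=shape2, block_max=block_max)
        for n in ns
    ]
    return _power_cells(cells, "n", ns, prior, effect_crit, samples, seed, quiet)


def power_curve(
    model: str,
    design: str,
    n: int = 20,
    delta_step: float = 0.05,
    prior: BetaParams = UNIFORM,
    effect_crit: float = 0.95,
    shape1: float = 1.0,
    shape2: float = 1.0,
    samples: int = 1000,
    block_max: float = 0.0,
    seed: int | None = None,
    quiet: bool = False,
) -> PowerTable:
    """Power at 21 separations 0, delta_step, ..., 20*delta_step for fixed n."""
    if delta_step <= 0:
        raise ValueError("delta_step must be positive")
    deltas = delta_step * np.arange(21)
    cells = [
        SimSpec(model=model, design=design, n=n, delta=float(d),
                shape1=shape1, shape2=shape2, block_max=block_max)
        for d in deltas
    ]
    return _power_cells(cells, "delta", deltas, prior, effect_crit, samples, seed, quiet)
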