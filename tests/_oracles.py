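"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dense grids, exhaustive enumeration,
python loops) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as _st


def hdi_grid_search(a: float, b: float, prob: float, step: float = 1e-5):
    """Narrowest interval of mass `prob` by dense search over lower bounds."""
    lo_masses = np.linspace(0.0, 1.0 - prob, int(round((1.0 - prob) / step)) + 1)
    lows = _st.beta.ppf(lo_masses, a, b)
    highs = _st.beta.ppf(lo_masses + prob, a, b)
    i = int(np.argmin(highs - lows))
    return float(lows[i]), float(highs[i])


def beta_interval_mass_by_integration(a, b, lo, hi, n_grid=1_000_000):
    """Mass of [lo, hi] under Beta(a, b) by trapezoid integration."""
    x = np.linspace(lo, hi, n_grid)
    return float(np.trapezoid(_st.beta.pdf(x, a, b), x))


def prob_x2_greater_x1(a1, b1, a2, b2, n_grid=2000):
    """P(X2 > X1) for independent betas by 2-D midpoint integration."""
    edges = np.linspace(0.0, 1.0, n_grid + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    w1 = np.diff(_st.beta.cdf(edges, a1, b1))
    w2 = np.diff(_st.beta.cdf(edges, a2, b2))
    gt = mids[None, :] > mids[:, None]  # [i, j] -> x2_j > x1_i
    return float(w1 @ gt @ w2)


def wilcoxon_enumeration_posterior(n: int, t_obs: int, grid: np.ndarray) -> np.ndarray:
    """Exact uniform-prior grid posterior for phi_w by enumerating 2^n sign vectors."""
    lik = np.zeros(grid.size)
    ranks = list(range(1, n + 1))
    for signs in itertools.product([0, 1], repeat=n):
        t_plus = sum(r for r, s in zip(ranks, signs) if s)
        if t_plus == t_obs:
            k = sum(signs)
            lik += grid**k * (1.0 - grid) ** (n - k)
    post = lik  # uniform prior: constant grid weights cancel
    return post / post.sum()


def midrank_sums_bruteforce(d):
    """T+/T- with midranks computed by explicit average-rank assignment."""
    d = [v for v in d if v != 0]
    absd = [abs(v) for v in d]
    order = sorted(range(len(d)), key=lambda i: absd[i])
    ranks = [0.0] * len(d)
    pos = 0
    while pos < len(order):
        run = [order[pos]]
        while pos + len(run) < len(order) and absd[order[pos + len(run)]] == absd[run[0]]:
            run.append(order[pos + len(run)])
        avg = sum(range(pos + 1, pos + len(run) + 1)) / len(run)
        for i in run:
            ranks[i] = avg
        pos += len(run)
    t_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    t_minus = sum(r for r, v in zip(ranks, d) if v < 0)
    return t_plus, t_minus


def pair_counts_bruteforce(x, y):
    """Concordant/discordant/tie bookkeeping by explicit pair loops."""
    n = len(x)
    n_c = n_d = both_tied = x_tied = y_tied = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                both_tied += 1
            elif dx == 0:
                x_tied += 1
            elif dy == 0:
                y_tied += 1
            elif (dx > 0) == (dy > 0):
                n_c += 1
            else:
                n_d += 1
    t_xy = both_tied
    t_x = x_tied + both_tied
    t_y = y_tied + both_tied
    return n_c, n_d, t_x, t_y, t_xy


def expand_table_to_points(table):
    """Replicate each cell (i, j) of a contingency table into rank pairs."""
    xs, ys = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            xs.extend([i + 1] * int(count))
            ys.extend([j + 1] * int(count))
    return xs, ys


def u_counts_bruteforce(e, c):
    u_e = sum(1 for a in e for b in c if a > b)
    u_c = sum(1 for a in e for b in c if b > a)
    return u_e, u_c
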