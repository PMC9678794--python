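"""Power calculations and descriptive group comparisons.

Power is for the Wald test of a single standard-normal continuous
predictor in logistic regression, on the standardized odds-ratio (sOR)
scale: with n subjects and overall event probability p, the Fisher
information for the predictor's coefficient at small effects is
approximately n*p*(1-p), giving

    power = Phi( |ln sOR| * sqrt(n*p*(1-p)) - z_{1-alpha/2} )

and, inverted, the minimum detectable effect

    ln sOR = (z_{1-alpha/2} + z_{power}) / sqrt(n*p*(1-p)).

A Monte-Carlo mode (simulate, fit, count Wald rejections) guards against
the approximation at larger effects.

Descriptive comparisons reproduce a baseline-characteristics table from
either raw data or printed summaries: two-sample t-tests (Welch by
default) computable from mean/SD/n alone, and Fisher's exact test for
2 x k contingency tables (hypergeometric for 2 x 2; full conditional
enumeration, i.e. the Freeman-Halton extension, for k > 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, gammaln
from scipy.stats import norm
from scipy.stats import fisher_exact as _fisher_2x2
from scipy.stats import ttest_ind_from_stats

import statsmodels.api as sm


@dataclass
class PowerQuery:
    n: int
    p_event: float
    alpha: float
    target_power: float | None = None
    sor: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.p_event < 1.0:
            raise ValueError("p_event must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sor is not None and self.sor <= 0:
            raise ValueError("sor must be positive")
        if self.target_power is not None and not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")


def power_at_sor(query: PowerQuery) -> float:
    """Wald-approximation power to detect a given standardized OR.

    Both rejection tails are counted, so at sOR = 1 the power equals the
    test's size alpha; away from the null the far tail is negligible and
    the formula reduces to Phi(|ln sOR|*sqrt(n p (1-p)) - z_{1-alpha/2}).
    """
    if query.sor is None:
        raise ValueError("power_at_sor requires query.sor")
    info = query.n * query.p_event * (1.0 - query.p_event)
    z_crit = norm.ppf(1.0 - query.alpha / 2.0)
    shift = abs(np.log(query.sor)) * np.sqrt(info)
    return float(norm.cdf(shift - z_crit) + norm.cdf(-shift - z_crit))


def min_detectable_sor(query: PowerQuery) -> tuple[float, float]:
    """Smallest sOR above 1 (and its reciprocal) reaching target power."""
    if query.target_power is None:
        raise ValueError("min_detectable_sor requires query.target_power")
    info = query.n * query.p_event * (1.0 - query.p_event)
    log_sor = (
        norm.ppf(1.0 - query.alpha / 2.0) + norm.ppf(query.target_power)
    ) / np.sqrt(info)
    upper = float(np.exp(log_sor))
    return upper, 1.0 / upper


def simulate_power(
    query: PowerQuery, n_replicates: int = 5000, seed: int = 0
) -> float:
    """Monte-Carlo power: simulate, fit the logistic model, count rejections.

    The predictor is standard normal; the intercept is solved so the
    marginal event probability equals ``p_event`` under the planted sOR.
    """
    if query.sor is None:
        raise ValueError("simulate_power requires query.sor")
    beta = float(np.log(query.sor))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    weights = weights / weights.sum()

    def marginal(b0: float) -> float:
        return float(weights @ expit(b0 + beta * nodes))

    b0 = brentq(lambda v: marginal(v) - query.p_event, -20, 20)

    rng = np.random.default_rng(seed)
    z_crit = norm.ppf(1.0 - query.alpha / 2.0)
    rejected = 0
    for _ in range(n_replicates):
        x = rng.standard_normal(query.n)
        y = (rng.random(query.n) < expit(b0 + beta * x)).astype(float)
        if y.min() == y.max():
            continue  # degenerate draw: no fit, no rejection
        res = sm.Logit(y, np.column_stack([np.ones(query.n), x])).fit(
            disp=0, maxiter=100
        )
        if abs(res.params[1]) / res.bse[1] > z_crit:
            rejected += 1
    return rejected / n_replicates


@dataclass
class SummaryRow:
    """mean +- SD summaries of one variable in cases and controls."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be at least 2")


def t_test_from_summary(
    row: SummaryRow, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Welch's form by default (``pooled=True`` for the equal-variance
    form).  Returns ``(t, df, p)``.
    """
    res = ttest_ind_from_stats(
        row.mean1, row.sd1, row.n1, row.mean2, row.sd2, row.n2,
        equal_var=pooled,
    )
    if pooled:
        df = row.n1 + row.n2 - 2.0
    else:
        v1, v2 = row.sd1 ** 2 / row.n1, row.sd2 ** 2 / row.n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (row.n1 - 1) + v2 ** 2 / (row.n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def round_p(p: float, digits: int = 3) -> float:
    """Round a p-value the way comparison tables print them."""
    return float(np.round(p, digits))


def _table_log_prob(table: np.ndarray) -> float:
    """Log conditional probability of a 2 x k table given its margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2 x k contingency table.

    For 2 x 2, the usual hypergeometric test; for k > 2 the
    Freeman-Halton extension: enumerate every 2 x k table with the
    observed margins and sum the conditional probabilities of tables no
    more probable than the observed one.  A zero row or column margin
    makes the table degenerate; p = 1 by convention.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return 1.0
    if table.shape[1] == 2:
        return float(_fisher_2x2(table, alternative="two-sided")[1])

    obs_lp = _table_log_prob(table)
    tol = 1e-9 * abs(obs_lp) + 1e-12
    r1 = int(row[0])
    k = table.shape[1]
    # log P(a_1..a_k | margins) = const + sum_j [-log a_j! - log(col_j - a_j)!]
    const = float(
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(table.sum() + 1)
    )
    col_tail = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])

    total = 0.0

    def recurse(j: int, remaining: int, lp_partial: float) -> None:
        nonlocal total
        if j == k - 1:
            a = remaining
            lp = const + lp_partial - gammaln(a + 1) - gammaln(col[j] - a + 1)
            if lp <= obs_lp + tol:
                total += float(np.exp(lp))
            return
        lo = max(0, remaining - int(col_tail[j]))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(
                j + 1,
                remaining - a,
                lp_partial - gammaln(a + 1) - gammaln(col[j] - a + 1),
            )

    recurse(0, r1, 0.0)
    return float(min(total, 1.0))


@dataclass
class ContingencyTable:
    """2 x k counts: rows are case/control, columns are categories."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2 or self.counts.shape[1] < 2:
            raise ValueError("counts must be 2 x k with k >= 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def fisher_p(self) -> float:
        return fisher_exact(self.counts)
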