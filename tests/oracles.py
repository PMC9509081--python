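"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact enumeration for
the rank tests and Fisher's exact test, per-gene statsmodels OLS for the
vectorized association fits, and a literal transcription of the
DerSimonian-Laird arithmetic for the meta-analysis hand example.
"""

from fractions import Fraction
from itertools import combinations, product
from math import comb

import numpy as np


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Exact rational hypergeometric probabilities; two-sided p sums the
    probabilities of all tables no more likely than the observed one
    (minimum-likelihood convention).
    """
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):  # table ((x, r1-x), (c1-x, r2-c1+x))
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating group assignments.

    Requires no ties.  Returns the doubled smaller tail of the exact
    Mann-Whitney U distribution, capped at 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def signed_rank_enumeration(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns.

    Requires non-zero differences with distinct magnitudes.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    assert np.all(d != 0) and len(np.unique(np.abs(d))) == len(d)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(lo, hi))


def ols_oracle(y, X):
    """Per-response OLS via statsmodels, returning (beta, se, p) for X[:,1]."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return fit.params[1], fit.bse[1], fit.pvalues[1]


def km_logrank_two_group_oracle(time, event, group):
    """Two-group log-rank chi-square from first principles (risk tables)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = np.unique(group)
    assert len(levels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == levels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == levels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def cox_partial_loglik(beta, time, event, x):
    """Log partial likelihood for one covariate, Breslow ties."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        ll += beta * x[dead].sum() - dead.sum() * np.log(
            np.exp(beta * x[risk]).sum())
    return ll
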