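"""Non-survival statistical evaluation.

Covers the three evaluation analyses around the classifier: predicting
observed log-odds CTC levels from the PCL-like score and tumor burden with a
sequential (Type-I) ANOVA variance decomposition; Wilcoxon group
comparisons; and Fisher's-exact co-occurrence of binary features with
Benjamini-Hochberg control and a sigmoid-scaled odds ratio for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import benjamini_hochberg

__all__ = [
    "CtcPredictionFit",
    "CooccurrenceCell",
    "predict_ctc",
    "compare_groups",
    "fisher_exact",
    "scaled_odds_ratio",
    "cooccurrence_matrix",
]


@dataclass
class CtcPredictionFit:
    """Linear model of observed log-odds CTC on PCL-like score and burden,
    with sequential sum-of-squares variance fractions (score entered first).
    """

    coef_score: float
    coef_burden: float
    intercept: float
    var_fraction_score: float
    var_fraction_burden: float
    var_fraction_residual: float
    adj_r2_obs_vs_pred: float
    n: int


@dataclass
class CooccurrenceCell:
    feature_a: str
    feature_b: str
    odds_ratio: float
    p_value: float
    q_value: float
    scaled_or: float
    continuity_corrected: bool = False


def predict_ctc(pcl_scores, logit_burden, logit_ctc_observed,
                score_first: bool = True) -> CtcPredictionFit:
    """OLS of observed log-odds CTC on PCL-like score + log-odds burden.

    Variance fractions come from a sequential (Type-I) decomposition with
    the PCL-like score entered first by default: each term's share is its
    incremental sum of squares over the total sum of squares, so the score,
    burden, and residual fractions sum to one.
    """
    s = np.asarray(pcl_scores, dtype=float)
    b = np.asarray(logit_burden, dtype=float)
    y = np.asarray(logit_ctc_observed, dtype=float)
    if not (s.shape == b.shape == y.shape):
        raise ValueError("inputs must be aligned 1-D vectors")
    keep = np.isfinite(s) & np.isfinite(b) & np.isfinite(y)
    s, b, y = s[keep], b[keep], y[keep]
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 complete observations, got {n}")
    if np.ptp(s) == 0:
        raise ValueError("constant predictor: pcl_scores")
    if np.ptp(b) == 0:
        raise ValueError("constant predictor: logit_burden")

    first, second = (s, b) if score_first else (b, s)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), first])
    X2 = np.column_stack([np.ones(n), first, second])
    if np.linalg.matrix_rank(X2) < 3:
        raise ValueError("collinear predictors: score and burden")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    rss0, _ = rss(X0)
    rss1, _ = rss(X1)
    rss2, beta = rss(X2)
    ss_total = rss0
    ss_first = rss0 - rss1
    ss_second = rss1 - rss2
    frac_first = ss_first / ss_total
    frac_second = ss_second / ss_total
    frac_resid = rss2 / ss_total

    fitted = X2 @ beta
    r2 = 1.0 - rss2 / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)

    if score_first:
        frac_score, frac_burden = frac_first, frac_second
        coef_score, coef_burden = beta[1], beta[2]
    else:
        frac_burden, frac_score = frac_first, frac_second
        coef_burden, coef_score = beta[1], beta[2]
    return CtcPredictionFit(
        coef_score=float(coef_score), coef_burden=float(coef_burden),
        intercept=float(beta[0]),
        var_fraction_score=float(frac_score),
        var_fraction_burden=float(frac_burden),
        var_fraction_residual=float(frac_resid),
        adj_r2_obs_vs_pred=float(adj_r2), n=n,
    )


def compare_groups(values_a, values_b, paired: bool = False):
    """Two-sided Wilcoxon test: signed-rank when paired, rank-sum otherwise.

    Exact rank-based p for small samples without ties (n <= 25), normal
    approximation with tie correction otherwise.  Returns
    ``(statistic, p_value, method)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal length")
        d = a - b
        has_ties = np.unique(np.abs(d[d != 0])).size < np.count_nonzero(d)
        exact = a.size <= 25 and not has_ties and np.all(d != 0)
        res = stats.wilcoxon(a, b, alternative="two-sided",
                             method="exact" if exact else "approx",
                             correction=not exact)
        return float(res.statistic), float(res.pvalue), (
            "wilcoxon_signed_rank_exact" if exact else "wilcoxon_signed_rank_normal")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(a.size, b.size) <= 25 and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue), (
        "wilcoxon_rank_sum_exact" if exact else "wilcoxon_rank_sum_normal")


def fisher_exact(table):
    """Fisher's exact test on a 2x2 table of non-negative integer counts.

    Two-sided p by the minimum-likelihood convention (sum of conditional
    hypergeometric probabilities no larger than the observed table's).
    Returns ``(odds_ratio, p_value, continuity_corrected)``: the sample odds
    ratio ad/bc, with 0.5 added to every cell for display only when a zero
    margin cell makes the ratio degenerate.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    corrected = False
    if b * c == 0 or a * d == 0:
        corrected = True
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return float(odds_ratio), float(res.pvalue), corrected


def scaled_odds_ratio(odds_ratio: float) -> float:
    """Logistic sigmoid of the log odds ratio: strictly increasing in the
    odds ratio, 0.5 at OR = 1, mapping (0, inf) onto (0, 1)."""
    if odds_ratio < 0:
        raise ValueError("odds ratio must be >= 0")
    if odds_ratio == 0:
        return 0.0
    return float(1.0 / (1.0 + np.exp(-np.log(odds_ratio))))


def cooccurrence_matrix(binary_features: pd.DataFrame,
                        fdr_cutoff: float = 0.05):
    """Pairwise co-occurrence of binary features by Fisher's exact test.

    All unordered feature pairs are tested on pairwise-complete samples,
    p-values are BH-adjusted across pairs, and cells with q below the cutoff
    are returned with the sigmoid-scaled odds ratio.  Pairs where a feature
    is single-level after missing-data removal are skipped and reported.

    Returns ``(cells, skipped)``.
    """
    feats = list(binary_features.columns)
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    raw = []
    skipped = []
    for fa, fb in combinations(feats, 2):
        sub = binary_features[[fa, fb]].dropna()
        x = sub[fa].astype(bool)
        y = sub[fb].astype(bool)
        if x.nunique() < 2 or y.nunique() < 2:
            skipped.append((fa, fb, "single level after missing-data removal"))
            continue
        tab = np.array([
            [int((x & y).sum()), int((x & ~y).sum())],
            [int((~x & y).sum()), int((~x & ~y).sum())],
        ])
        or_, p, corr = fisher_exact(tab)
        raw.append((fa, fb, or_, p, corr))
    if not raw:
        return [], skipped
    q = benjamini_hochberg([r[3] for r in raw])
    cells = [
        CooccurrenceCell(fa, fb, or_, p, float(qv), scaled_odds_ratio(or_), corr)
        for (fa, fb, or_, p, corr), qv in zip(raw, q)
        if qv < fdr_cutoff
    ]
    return cells, skipped
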