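"""Gene ranking by association with CTC level, adjusted for tumor burden.

Each gene's log-scale expression is regressed (OLS) on an intercept, the
log-odds CTC fraction, and the log-odds bone-marrow plasmacytosis.  The CTC
coefficient is the expression change per log-odds unit increase in CTC level
independent of tumor burden; genes are ranked by the two-sided t-test
p-value of that coefficient, with Benjamini-Hochberg control of the false
discovery rate across all tested genes.

Samples with undetectable CTC are excluded from fitting by default (the
association is defined over samples with a measured CTC fraction); an
option imputes half the detection limit instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DEFAULT_LOGIT_EPS, ExpressionMatrix, logit

__all__ = [
    "GeneAssociation",
    "fit_gene_model",
    "fit_gene_models",
    "benjamini_hochberg",
    "rank_genes",
]

#: half the reported flow limit of detection, used when imputing
#: undetectable CTC instead of excluding those samples
LOD_HALF = 0.5e-5


@dataclass
class GeneAssociation:
    """Per-gene association with log-odds CTC level, burden-adjusted."""

    gene_id: str
    beta_ctc: float   # expression change per log-odds CTC unit ("logFC")
    se_ctc: float
    beta_burden: float
    p_value: float
    q_value: float | None
    n_used: int


def _design(logit_ctc: np.ndarray, logit_burden: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(logit_ctc), logit_ctc, logit_burden])


def _check_collinear(X: np.ndarray) -> None:
    names = ("intercept", "logit_ctc", "logit_burden")
    for j in (1, 2):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"degenerate design: column {names[j]!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: columns are collinear")


def fit_gene_models(expr: np.ndarray, logit_ctc: np.ndarray,
                    logit_burden: np.ndarray):
    """Vectorized OLS of many genes on (1, logit_ctc, logit_burden).

    ``expr`` is (n_genes, n_samples).  Samples with a missing covariate are
    dropped (expression itself must be complete).  Returns a DataFrame-ready
    dict of arrays: beta_ctc, se_ctc, beta_burden, p_value, n_used.
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    logit_ctc = np.asarray(logit_ctc, dtype=float)
    logit_burden = np.asarray(logit_burden, dtype=float)
    keep = np.isfinite(logit_ctc) & np.isfinite(logit_burden)
    n = int(keep.sum())
    if n < 4:
        raise ValueError(f"need at least 4 complete samples, got {n}")
    X = _design(logit_ctc[keep], logit_burden[keep])
    _check_collinear(X)
    Y = expr[:, keep]

    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T                      # (n_genes, 3)
    resid = Y - B @ X.T
    df = n - 3
    sigma2 = (resid ** 2).sum(axis=1) / df
    se_ctc = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_ctc > 0, B[:, 1] / se_ctc, np.inf * np.sign(B[:, 1]))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(t), 1.0, p)          # exactly-zero gene: no evidence
    return {
        "beta_ctc": B[:, 1],
        "se_ctc": se_ctc,
        "beta_burden": B[:, 2],
        "p_value": p,
        "n_used": np.full(expr.shape[0], n),
    }


def fit_gene_model(expr_g, logit_ctc, logit_burden, gene_id: str = "gene") -> GeneAssociation:
    """OLS fit of one gene's expression on intercept + logit CTC + logit burden.

    Samples missing any of the three values are dropped pairwise; the CTC
    coefficient carries a two-sided t-test p-value on n - 3 degrees of
    freedom (no moderated variance).
    """
    expr_g = np.asarray(expr_g, dtype=float)
    logit_ctc = np.asarray(logit_ctc, dtype=float)
    logit_burden = np.asarray(logit_burden, dtype=float)
    if not expr_g.shape == logit_ctc.shape == logit_burden.shape:
        raise ValueError("expr, logit_ctc, logit_burden must be aligned")
    keep = np.isfinite(expr_g) & np.isfinite(logit_ctc) & np.isfinite(logit_burden)
    res = fit_gene_models(expr_g[keep][None, :], logit_ctc[keep], logit_burden[keep])
    return GeneAssociation(
        gene_id=gene_id,
        beta_ctc=float(res["beta_ctc"][0]),
        se_ctc=float(res["se_ctc"][0]),
        beta_burden=float(res["beta_burden"][0]),
        p_value=float(res["p_value"][0]),
        q_value=None,
        n_used=int(res["n_used"][0]),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving.

    q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / j, clipped to 1; ties handled
    by stable sort so equal p-values receive equal q-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_genes(matrix: ExpressionMatrix, annotation: pd.DataFrame,
               fdr_cutoff: float = 0.05, *, eps: float = DEFAULT_LOGIT_EPS,
               include_ppcl: bool = True,
               impute_undetectable: bool = False):
    """Rank all genes by burden-adjusted association with log-odds CTC level.

    Parameters
    ----------
    matrix : expression, genes by samples.
    annotation : table indexed by (or containing) sample_id with columns
        ``ctc_fraction``, ``burden_fraction`` and optionally
        ``ctc_detectable`` and ``disease_label``.
    fdr_cutoff : BH q-value threshold defining the significant subset.
    include_ppcl : when False, restrict fitting to NDMM samples.
    impute_undetectable : replace undetectable CTC with half the detection
        limit instead of excluding those samples.

    Returns
    -------
    (ranking, significant) : DataFrames ordered by ascending p-value, ties
    broken by descending \\|beta_ctc\\| then gene id.
    """
    annot = annotation.copy()
    if "sample_id" in annot.columns:
        annot = annot.set_index("sample_id")
    missing = matrix.sample_ids.difference(annot.index)
    if len(missing):
        raise ValueError(f"annotation missing sample {missing[0]!r}")
    annot = annot.loc[matrix.sample_ids]

    ctc = annot["ctc_fraction"].to_numpy(float)
    burden = annot["burden_fraction"].to_numpy(float)
    if "ctc_detectable" in annot.columns:
        undet = ~annot["ctc_detectable"].fillna(True).astype(bool).to_numpy()
        if impute_undetectable:
            ctc = np.where(undet, LOD_HALF, ctc)
        else:
            ctc = np.where(undet, np.nan, ctc)
    if not include_ppcl and "disease_label" in annot.columns:
        ctc = np.where(annot["disease_label"].to_numpy() == "pPCL", np.nan, ctc)

    eligible = np.isfinite(ctc) & np.isfinite(burden)
    if not eligible.any():
        raise ValueError("no eligible samples: all lack detectable CTC or burden")

    lc = np.where(np.isfinite(ctc), logit(np.nan_to_num(ctc, nan=0.5), eps), np.nan)
    lb = np.where(np.isfinite(burden), logit(np.nan_to_num(burden, nan=0.5), eps), np.nan)
    res = fit_gene_models(matrix.values, lc, lb)

    ranking = pd.DataFrame(res, index=matrix.gene_ids)
    ranking["q_value"] = benjamini_hochberg(ranking["p_value"].to_numpy())
    ranking = (
        ranking.reset_index()
        .assign(_abs_beta=lambda d: d["beta_ctc"].abs())
        .sort_values(["p_value", "_abs_beta", "gene_id"],
                     ascending=[True, False, True], kind="stable")
        .drop(columns="_abs_beta")
        .set_index("gene_id")
    )
    significant = ranking[ranking["q_value"] < fdr_cutoff]
    return ranking, significant
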