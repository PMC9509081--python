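"""PCL-like score construction, calibration, packaging, and application.

The classifier is built in three steps: (1) genes are ranked by their
association with the log-odds CTC level adjusted for tumor burden
(:mod:`pclike.association`); (2) the number of genes is chosen by
leave-one-out cross-validation, scoring each held-out sample with a model
rebuilt on the remaining samples and taking the smallest gene count that
maximizes the held-out ROC AUC for pPCL vs NDMM; (3) the decision threshold
is the minimal score among discovery pPCL samples (over both in-sample and
out-of-fold scores, see :func:`build_classifier`), so discovery pPCL
sensitivity is 100% by construction, and the classification rule is
inclusive (score >= threshold => PCL-like).

A sample's score is the equal-weight signed mean of its training-set
standardized expression over the model genes; the serialized model schema
carries per-gene real weights so externally estimated coefficients can be
dropped in without code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .association import rank_genes
from .io import DEFAULT_LOGIT_EPS, ExpressionMatrix

__all__ = [
    "PclClassifierModel",
    "ScoredSample",
    "CoverageError",
    "compute_score",
    "score_samples",
    "loocv_select_size",
    "calibrate_threshold",
    "build_classifier",
    "save_model",
    "load_model",
    "load_packaged_model",
    "PACKAGED_MODEL_RESOURCE",
    "PclLikeClassifier",
]

PACKAGED_MODEL_RESOURCE = "pcl54_model_synthetic.json"


class CoverageError(ValueError):
    """Too few model genes present in the sample's gene space."""


@dataclass
class PclClassifierModel:
    """An ordered gene set with signs/weights, standardization statistics,
    and a decision threshold."""

    genes: list[str]
    signs: np.ndarray                      # +1 / -1 per gene
    weights: np.ndarray                    # real weight per gene
    threshold: float
    train_stats: pd.DataFrame | None = None  # columns mean, sd; index gene_id
    provenance: str = "built"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("model must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            seen = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id in model: {dup!r}")
        if not (len(self.genes) == self.signs.size == self.weights.size):
            raise ValueError("genes, signs, weights must be aligned")
        if not np.all(np.isin(self.signs, (-1.0, 1.0))):
            raise ValueError("signs must be +1 or -1")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class ScoredSample:
    sample_id: str
    pcl_score: float
    call: str                 # "PCL-like" | "not-PCL-like"
    n_genes_used: int
    n_genes_missing: int


def _standardize_for_model(model: PclClassifierModel,
                           expression: pd.DataFrame,
                           reference_stats: pd.DataFrame | None):
    """Align a genes-by-samples frame to the model genes and z-score them.

    Returns (z, used_mask) with z of shape (n_model_genes, n_samples); rows
    for genes absent from the expression frame are NaN.
    """
    stats = reference_stats if reference_stats is not None else model.train_stats
    if stats is None:
        raise ValueError(
            "model carries no train_stats; supply reference_stats from a "
            "declared reference cohort"
        )
    present = np.array([g in expression.index and g in stats.index
                        for g in model.genes])
    z = np.full((model.n_genes, expression.shape[1]), np.nan)
    if present.any():
        genes = [g for g, ok in zip(model.genes, present) if ok]
        mean = stats.loc[genes, "mean"].to_numpy(float)
        sd = stats.loc[genes, "sd"].to_numpy(float)
        z[present] = (expression.loc[genes].to_numpy(float) - mean[:, None]) / sd[:, None]
    return z, present


def compute_score(model: PclClassifierModel, sample_expression,
                  reference_stats: pd.DataFrame | None = None,
                  min_coverage: float = 0.5,
                  sample_id: str = "sample") -> ScoredSample:
    """Score one sample: signed, weighted mean of standardized expression.

    ``sample_expression`` maps gene id to log-scale expression (a pandas
    Series or dict).  Missing model genes are skipped and counted; fewer
    than ``min_coverage`` of the model genes present raises
    :class:`CoverageError`.
    """
    s = pd.Series(sample_expression, dtype=float)
    frame = s.to_frame(name=sample_id)
    z, present = _standardize_for_model(model, frame, reference_stats)
    k = int(present.sum())
    if k < min_coverage * model.n_genes or k == 0:
        raise CoverageError(
            f"only {k}/{model.n_genes} model genes available for "
            f"{sample_id!r} (minimum coverage {min_coverage:.0%})"
        )
    contrib = model.signs[present] * model.weights[present] * z[present, 0]
    score = float(contrib.mean())
    call = "PCL-like" if score >= model.threshold else "not-PCL-like"
    return ScoredSample(sample_id, score, call, k, model.n_genes - k)


def score_samples(model: PclClassifierModel, matrix: ExpressionMatrix,
                  reference_stats: pd.DataFrame | None = None,
                  min_coverage: float = 0.5) -> pd.DataFrame:
    """Score every sample of a matrix; returns a DataFrame indexed by
    sample_id with columns pcl_score, call, n_genes_used, n_genes_missing."""
    frame = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                         columns=matrix.sample_ids)
    z, present = _standardize_for_model(model, frame, reference_stats)
    k = int(present.sum())
    if k < min_coverage * model.n_genes or k == 0:
        raise CoverageError(
            f"only {k}/{model.n_genes} model genes available "
            f"(minimum coverage {min_coverage:.0%})"
        )
    contrib = (model.signs[present, None] * model.weights[present, None]
               * z[present, :])
    scores = contrib.mean(axis=0)
    return pd.DataFrame(
        {
            "pcl_score": scores,
            "call": np.where(scores >= model.threshold, "PCL-like", "not-PCL-like"),
            "n_genes_used": k,
            "n_genes_missing": model.n_genes - k,
        },
        index=matrix.sample_ids,
    )


def calibrate_threshold(ppcl_scores) -> float:
    """Decision threshold: the minimal PCL-like score among discovery pPCL
    samples, so every discovery pPCL sample is called PCL-like."""
    arr = np.asarray(list(np.atleast_1d(ppcl_scores)), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one pPCL score is required")
    return float(arr.min())


def _ranked_fit(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                eps: float):
    """Rank genes and return (ordered gene indices, signs, means, sds)."""
    ranking, _ = rank_genes(matrix, annotation, fdr_cutoff=1.0, eps=eps)
    order = matrix.gene_ids.get_indexer(ranking.index)
    signs = np.sign(ranking["beta_ctc"].to_numpy(float))
    signs[signs == 0] = 1.0
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    return order, signs, mean, sd


def loocv_select_size(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                      size_grid=(10, 25, 54, 100), *,
                      eps: float = DEFAULT_LOGIT_EPS,
                      rerank_per_fold: bool = True,
                      return_fold_details: bool = False):
    """Choose the classifier gene count by leave-one-out cross-validation.

    For each left-out sample the remaining samples are re-ranked (unless
    ``rerank_per_fold`` is False, the fast mode that ranks once on the full
    data and cross-validates only the standardization and score), a top-k
    model is formed for every k in ``size_grid``, and the held-out sample is
    scored.  Per-k performance is the ROC AUC of held-out scores for pPCL vs
    NDMM; the selected size is the smallest k attaining the maximum.

    Returns ``(k_star, table)`` where table has columns k and auc; with
    ``return_fold_details`` a third element gives each fold's gene ranking.
    """
    size_grid = sorted(int(k) for k in set(size_grid))
    if not size_grid:
        raise ValueError("size_grid must be non-empty")
    if max(size_grid) > matrix.n_genes:
        raise ValueError("size_grid exceeds the number of genes")
    annot = annotation.copy()
    if "sample_id" in annot.columns:
        annot = annot.set_index("sample_id")
    annot = annot.loc[matrix.sample_ids]
    y = (annot["disease_label"].to_numpy() == "pPCL")
    if not y.any() or y.all():
        raise ValueError("LOOCV needs both pPCL and NDMM samples")

    n = matrix.n_samples
    if not rerank_per_fold:
        full_order, full_signs, _, _ = _ranked_fit(matrix, annot, eps)

    held_scores = np.full((n, len(size_grid)), np.nan)
    fold_rankings = []
    skipped = 0
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        sub = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids[train_idx],
                               matrix.values[:, train_idx], matrix.platform)
        try:
            if rerank_per_fold:
                order, signs, mean, sd = _ranked_fit(
                    sub, annot.iloc[train_idx], eps)
            else:
                order, signs = full_order, full_signs
                mean = sub.values.mean(axis=1)
                sd = sub.values.std(axis=1, ddof=1)
                sd[sd == 0] = 1.0
        except ValueError:
            skipped += 1
            fold_rankings.append(None)
            continue
        z = (matrix.values[:, i] - mean) / sd
        signed = signs * z[order]
        cummean = np.cumsum(signed) / np.arange(1, len(signed) + 1)
        held_scores[i] = cummean[np.array(size_grid) - 1]
        fold_rankings.append(matrix.gene_ids[order])
    if skipped > 0.10 * n:
        raise ValueError(f"{skipped}/{n} LOOCV folds skipped (degenerate designs)")

    valid = ~np.isnan(held_scores[:, 0])
    aucs = [roc_auc_score(y[valid], held_scores[valid, j])
            for j in range(len(size_grid))]
    table = pd.DataFrame({"k": size_grid, "auc": aucs})
    k_star = int(table.loc[table["auc"] == table["auc"].max(), "k"].min())
    if return_fold_details:
        details = {
            "fold_rankings": fold_rankings,
            "held_scores": pd.DataFrame(held_scores, index=matrix.sample_ids,
                                        columns=size_grid),
        }
        return k_star, table, details
    return k_star, table


def build_classifier(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                     fdr_cutoff: float = 0.05,
                     size_grid=(10, 25, 54, 100), *,
                     eps: float = DEFAULT_LOGIT_EPS,
                     rerank_per_fold: bool = True) -> PclClassifierModel:
    """Compose the three construction steps into a finished model.

    Genes are ranked on the full discovery set, the gene count comes from
    LOOCV, weights are 1 with signs from the training CTC coefficient, and
    standardization statistics come from the discovery set.  The threshold
    is the minimal discovery pPCL score over both in-sample and
    leave-one-out (out-of-fold) scores: the in-sample minimum alone is
    optimistically inflated because gene selection favors genes whose noise
    aligns with the high-leverage pPCL samples, and a threshold calibrated
    on it generalizes poorly; taking the minimum over both keeps discovery
    pPCL sensitivity at 100% by construction while protecting new-cohort
    sensitivity from selection optimism.
    """
    annot = annotation.copy()
    if "sample_id" in annot.columns:
        annot = annot.set_index("sample_id")
    annot = annot.loc[matrix.sample_ids]

    ranking, significant = rank_genes(matrix, annot, fdr_cutoff, eps=eps)
    k_star, table, details = loocv_select_size(
        matrix, annot, size_grid, eps=eps,
        rerank_per_fold=rerank_per_fold, return_fold_details=True)
    top = ranking.head(k_star)
    genes = list(top.index)
    signs = np.sign(top["beta_ctc"].to_numpy(float))
    signs[signs == 0] = 1.0
    sub = matrix.subset_genes(genes)
    mean = sub.values.mean(axis=1)
    sd = sub.values.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    train_stats = pd.DataFrame({"mean": mean, "sd": sd}, index=pd.Index(genes, name="gene_id"))

    model = PclClassifierModel(
        genes=genes, signs=signs, weights=np.ones(k_star),
        threshold=0.0, train_stats=train_stats, provenance="built",
        metadata={
            "n_discovery_samples": int(matrix.n_samples),
            "n_genes_tested": int(matrix.n_genes),
            "n_significant": int(len(significant)),
            "fdr_cutoff": fdr_cutoff,
            "k_star": k_star,
            "loocv_auc": table.set_index("k")["auc"].to_dict(),
        },
    )
    scored = score_samples(model, matrix)
    ppcl = (annot["disease_label"] == "pPCL").to_numpy()
    insample = calibrate_threshold(scored.loc[ppcl, "pcl_score"])
    heldout = details["held_scores"].loc[ppcl, k_star].dropna()
    model.threshold = min(insample, calibrate_threshold(heldout)) \
        if len(heldout) else insample
    return model


def save_model(model: PclClassifierModel, path) -> None:
    payload = {
        "provenance": model.provenance,
        "threshold": model.threshold,
        "metadata": model.metadata,
        "genes": [
            {"gene_id": g, "sign": int(s), "weight": float(w)}
            for g, s, w in zip(model.genes, model.signs, model.weights)
        ],
    }
    if model.train_stats is not None:
        payload["train_stats"] = {
            g: {"mean": float(m), "sd": float(s)}
            for g, (m, s) in model.train_stats[["mean", "sd"]].iterrows()
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def _model_from_payload(payload: dict) -> PclClassifierModel:
    genes = [e["gene_id"] for e in payload["genes"]]
    signs = np.array([e["sign"] for e in payload["genes"]], dtype=float)
    weights = np.array([e.get("weight", 1.0) for e in payload["genes"]], dtype=float)
    stats = None
    if payload.get("train_stats"):
        stats = pd.DataFrame(payload["train_stats"]).T
        stats.index.name = "gene_id"
    return PclClassifierModel(
        genes=genes, signs=signs, weights=weights,
        threshold=float(payload["threshold"]), train_stats=stats,
        provenance=payload.get("provenance", "built"),
        metadata=payload.get("metadata", {}),
    )


def load_model(path) -> PclClassifierModel:
    """Load a serialized model from a JSON file."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    return _model_from_payload(payload)


def load_packaged_model(path=None) -> PclClassifierModel:
    """Load the packaged 54-gene PCL-like classifier (threshold 3.55).

    The packaged gene table is a synthetic stand-in: the published
    identifiers live in a table that is not machine-readable here, so the
    fixture carries the CTC-associated genes named in the study's prose plus
    placeholder identifiers, 54 entries total.  Standardization statistics
    are intentionally absent — scoring requires a user-declared reference
    cohort (the original cohort's per-gene means and sds are unpublished).
    """
    if path is not None:
        model = load_model(path)
    else:
        ref = resources.files("pclike").joinpath("data", PACKAGED_MODEL_RESOURCE)
        model = _model_from_payload(json.loads(ref.read_text()))
    return model


class PclLikeClassifier(BaseEstimator):
    """Scikit-learn style estimator wrapping classifier construction.

    Parameters
    ----------
    fdr_cutoff : BH q-value threshold for the gene-association step.
    size_grid : candidate gene counts for the LOOCV size search.
    rerank_per_fold : re-rank genes inside each LOOCV fold (avoids
        selection bias); False is a fast mode that ranks once.
    min_coverage : minimum fraction of model genes required to score.
    eps : clamp for the log-odds transform of fractions.

    ``fit`` expects ``X`` as a samples-by-genes DataFrame and ``y`` as
    disease labels ("pPCL" / "NDMM"), with CTC and burden fractions passed
    as fit parameters.  Fitted attributes: ``model_``, ``k_``,
    ``loocv_results_``, ``ranking_``, ``threshold_``.
    ``decision_function`` returns PCL-like scores; ``predict`` returns
    "PCL-like" / "not-PCL-like" calls with the inclusive >= rule.
    """

    def __init__(self, fdr_cutoff: float = 0.05,
                 size_grid=(10, 25, 54, 100),
                 rerank_per_fold: bool = True,
                 min_coverage: float = 0.5,
                 eps: float = DEFAULT_LOGIT_EPS):
        self.fdr_cutoff = fdr_cutoff
        self.size_grid = size_grid
        self.rerank_per_fold = rerank_per_fold
        self.min_coverage = min_coverage
        self.eps = eps

    def fit(self, X: pd.DataFrame, y, *, ctc_fraction, burden_fraction):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples-by-genes DataFrame")
        matrix = ExpressionMatrix(X.columns, X.index, X.to_numpy(float).T)
        annot = pd.DataFrame(
            {
                "disease_label": np.asarray(y),
                "ctc_fraction": np.asarray(ctc_fraction, dtype=float),
                "burden_fraction": np.asarray(burden_fraction, dtype=float),
            },
            index=matrix.sample_ids,
        )
        self.model_ = build_classifier(
            matrix, annot, self.fdr_cutoff, self.size_grid,
            eps=self.eps, rerank_per_fold=self.rerank_per_fold)
        self.k_ = self.model_.n_genes
        self.threshold_ = self.model_.threshold
        self.loocv_results_ = pd.DataFrame(
            {"k": list(self.model_.metadata["loocv_auc"]),
             "auc": list(self.model_.metadata["loocv_auc"].values())})
        self.ranking_ = None  # full table available via association.rank_genes
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        matrix = ExpressionMatrix(X.columns, X.index, X.to_numpy(float).T)
        scored = score_samples(self.model_, matrix,
                               min_coverage=self.min_coverage)
        return scored["pcl_score"].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= self.model_.threshold,
                        "PCL-like", "not-PCL-like")
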