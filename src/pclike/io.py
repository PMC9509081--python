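"""Expression-matrix and annotation I/O, the log-odds transform, and
gene-level standardization.

Expression values are assumed to be on a log scale and already normalized
within each platform; cross-platform normalization is out of scope.  The
circulating-tumor-cell (CTC) fraction and the bone-marrow plasmacytosis
(tumor burden) are both modeled on the log-odds (logit) scale throughout the
pipeline, with an epsilon clamp so undetectable CTC maps to a finite,
extreme log-odds value (the flow assay's limit of detection is below 1e-5,
so the default clamp of 1e-6 sits under it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_annotation",
    "logit",
    "DEFAULT_LOGIT_EPS",
    "filter_expressed",
    "GeneStandardizer",
    "standardize_genes",
    "validate_annotation",
    "DISEASE_LABELS",
]

DEFAULT_LOGIT_EPS = 1e-6

DISEASE_LABELS = ("healthy", "MGUS", "SMM", "NDMM", "pPCL", "PD")

#: annotation columns the pipeline understands
ANNOTATION_COLUMNS = (
    "sample_id",
    "ctc_fraction",
    "ctc_detectable",
    "burden_fraction",
    "disease_label",
    "study_id",
    "age_le_65",
)


class ParseError(ValueError):
    """Malformed expression or annotation input."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes in rows and samples in columns.

    Parameters
    ----------
    gene_ids : ordered gene identifiers (HGNC symbols or Ensembl gene IDs,
        Ensembl release-74 dialect).
    sample_ids : ordered sample identifiers.
    values : (n_genes, n_samples) float array of log-scale expression.
    platform : one of ``microarray``, ``rnaseq``, ``synthetic``.
    """

    gene_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray
    platform: str = "synthetic"

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.sample_ids = pd.Index(self.sample_ids, name="sample_id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()][0]
            raise ParseError(f"duplicate gene identifier: {dup!r}")
        if self.sample_ids.has_duplicates:
            dup = self.sample_ids[self.sample_ids.duplicated()][0]
            raise ParseError(f"duplicate sample identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame view (copy)."""
        return pd.DataFrame(self.values.copy(), index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, platform: str = "synthetic") -> "ExpressionMatrix":
        return cls(frame.index, frame.columns, frame.to_numpy(dtype=float), platform)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_ids.get_indexer(genes)
        if (idx < 0).any():
            missing = pd.Index(genes)[idx < 0][0]
            raise KeyError(f"gene not in matrix: {missing!r}")
        return ExpressionMatrix(pd.Index(genes), self.sample_ids,
                                self.values[idx], self.platform)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = self.sample_ids.get_indexer(samples)
        if (idx < 0).any():
            missing = pd.Index(samples)[idx < 0][0]
            raise KeyError(f"sample not in matrix: {missing!r}")
        return ExpressionMatrix(self.gene_ids, pd.Index(samples),
                                self.values[:, idx], self.platform)


def read_expression(path, format: str = "tsv", platform: str = "synthetic") -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene id, header sample ids)."""
    if format != "tsv":
        raise ValueError(f"unsupported format: {format!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    if frame.columns.size == 0:
        raise ParseError(f"{path}: header contains no sample columns")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][0]
            raise ParseError(
                f"{path}: non-numeric cell at gene {bad!r}, sample {col!r}"
            )
    try:
        return ExpressionMatrix.from_frame(frame, platform=platform)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write genes-by-samples TSV at full float precision (round-trip safe)."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample annotation table; returns it indexed by sample_id.

    Raises :class:`ParseError` naming the offending column/sample for
    out-of-range fractions, unknown disease labels, or duplicate sample ids.
    """
    annot = annotation.copy()
    if "sample_id" in annot.columns:
        annot = annot.set_index("sample_id")
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()][0]
        raise ParseError(f"duplicate sample identifier in annotation: {dup!r}")
    for col in ("ctc_fraction", "burden_fraction"):
        if col in annot.columns:
            vals = annot[col].astype(float)
            bad = vals[(vals < 0) | (vals > 1)].dropna()
            if len(bad):
                raise ParseError(
                    f"{col} outside [0, 1] for sample {bad.index[0]!r}: {bad.iloc[0]}"
                )
    if "disease_label" in annot.columns:
        unknown = set(annot["disease_label"].dropna()) - set(DISEASE_LABELS)
        if unknown:
            raise ParseError(f"unknown disease label(s): {sorted(unknown)}")
    return annot


def read_annotation(path) -> pd.DataFrame:
    """Read and validate a per-sample annotation CSV."""
    return validate_annotation(pd.read_csv(path))


def logit(p, eps: float = DEFAULT_LOGIT_EPS):
    """Log-odds transform with clamping: ln(p'/(1-p')), p' = clip(p, eps, 1-eps).

    The clamp keeps zero fractions (e.g. undetectable CTC) finite on the
    log-odds scale.  Accepts scalars or arrays; NaN passes through so missing
    fractions stay missing.
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    arr = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((arr < 0) | (arr > 1)):
            bad = arr[(arr < 0) | (arr > 1)].flat[0]
            raise ValueError(f"fraction outside [0, 1]: {bad}")
    clipped = np.clip(arr, eps, 1.0 - eps)
    out = np.log(clipped / (1.0 - clipped))
    return out if out.ndim else float(out)


def filter_expressed(matrix: ExpressionMatrix, min_fraction_expressed: float = 0.5,
                     min_level: float = 0.0) -> ExpressionMatrix:
    """Keep genes expressed above ``min_level`` in at least
    ``min_fraction_expressed`` of samples; gene order preserved.

    The discovery analysis operates on the "expressed" gene set; the exact
    rule is a tunable choice, with a fraction-of-samples threshold as the
    default.
    """
    if not 0 <= min_fraction_expressed <= 1:
        raise ValueError("min_fraction_expressed must be in [0, 1]")
    frac = (matrix.values > min_level).mean(axis=1)
    keep = frac >= min_fraction_expressed
    if not keep.any():
        raise ValueError("no genes pass filter")
    return ExpressionMatrix(matrix.gene_ids[keep], matrix.sample_ids,
                            matrix.values[keep], matrix.platform)


class GeneStandardizer(TransformerMixin, BaseEstimator):
    """Per-gene centering and scaling by training-set statistics.

    Operates on genes-by-samples arrays (axis 1 = samples), mirroring how
    classifier scores standardize each gene by the declared training cohort
    before combining them.  Zero-variance genes are assigned sd = 1 and
    recorded in ``zero_variance_genes_`` with a warning.

    Attributes
    ----------
    mean_ : (n_genes,) per-gene training means
    scale_ : (n_genes,) per-gene training standard deviations (ddof=1)
    zero_variance_genes_ : indices of genes flagged with sd = 0
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D genes-by-samples array")
        self.mean_ = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1) if X.shape[1] > 1 else np.zeros(X.shape[0])
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            warnings.warn(
                f"{zero.size} zero-variance gene(s) assigned sd = 1",
                UserWarning, stacklevel=2,
            )
            sd = sd.copy()
            sd[zero] = 1.0
        self.scale_ = sd
        self.zero_variance_genes_ = zero
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.mean_.shape[0]:
            raise ValueError(
                f"gene dimension {X.shape[0]} does not match fitted "
                f"{self.mean_.shape[0]}"
            )
        return (X - self.mean_[:, None]) / self.scale_[:, None]


def standardize_genes(matrix: ExpressionMatrix, reference_stats: pd.DataFrame | None = None):
    """Standardize each gene; returns ``(standardized_matrix, stats)``.

    ``reference_stats`` is a DataFrame indexed by gene id with columns
    ``mean`` and ``sd`` (training-set statistics); when omitted, statistics
    are estimated from ``matrix`` itself and returned so that validation
    samples can reuse them.
    """
    if reference_stats is not None:
        missing = matrix.gene_ids.difference(reference_stats.index)
        if len(missing):
            raise ValueError(f"reference_stats missing gene {missing[0]!r}")
        mean = reference_stats.loc[matrix.gene_ids, "mean"].to_numpy(float)
        sd = reference_stats.loc[matrix.gene_ids, "sd"].to_numpy(float)
        if np.any(sd <= 0):
            raise ValueError("reference_stats sd must be positive")
        z = (matrix.values - mean[:, None]) / sd[:, None]
        stats = reference_stats.loc[matrix.gene_ids, ["mean", "sd"]]
    else:
        scaler = GeneStandardizer().fit(matrix.values)
        z = scaler.transform(matrix.values)
        stats = pd.DataFrame(
            {"mean": scaler.mean_, "sd": scaler.scale_}, index=matrix.gene_ids
        )
    out = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, z, matrix.platform)
    return out, stats
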