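"""Synthetic bulk-expression cohorts with the statistical structure the
PCL-like analysis assumes.

A latent "PCL-likeness" factor drives both the circulating-tumor-cell (CTC)
level (on the log-odds scale) and the expression of a designated set of
signal genes, so signal genes are recoverable ground truth.  The latent
factor is a two-component mixture: a background population centered at zero
and a minority PCL-like subpopulation with a shifted mean, emulating the
separately enrolled leukemic patients whose CTC levels sit far above the
clinical cutoff.  Tumor burden (bone-marrow plasmacytosis) is drawn from a
Beta distribution and feeds the CTC level weakly and positively; a second
block of "confounded" genes responds to burden only, and the remainder are
pure noise.  Samples whose CTC fraction reaches the 20% cutoff are labeled
pPCL, mirroring the clinical rule; all others are NDMM.  Survival times are
exponential with the hazard multiplied by a configurable ratio for truly
PCL-like (subpopulation) samples, under independent uniform censoring.

Defaults mirror the discovery-cohort conditions: 110 samples, 2,000 genes of
which 100 carry signal, a 12% PCL-like subpopulation placing roughly 10% of
samples above the pPCL cutoff overall (the background alone exceeds it ~2%
of the time), NDMM-like median CTC near 0.02%, subpopulation median CTC
near 30%, and a weak positive burden-CTC association (adjusted R-squared
near 0.12).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io import ExpressionMatrix, logit

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ConfigurationError",
    "generate_cohort",
    "generate_multistudy",
    "apply_platform_distortion",
    "write_cohort",
]

#: fixed offsets added to the master seed per generation stage
STAGE_SEED_EXPRESSION = 0
STAGE_SEED_SURVIVAL = 1
STAGE_SEED_PLATFORM = 2


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Attributes
    ----------
    n_samples, n_genes : cohort dimensions.
    n_signal_genes : genes driven by the latent PCL-likeness factor (which
        enters the log-odds CTC level with unit coefficient).
    signal_effect : expression change per latent log-odds unit for signal
        genes (the generative counterpart of the reported "logFC"; the
        estimated per-log-odds-CTC slope is slightly attenuated by CTC
        measurement noise).
    n_confounded_genes, burden_effect : genes driven by log-odds tumor
        burden only, and their per-unit slope.
    noise_sd : per-gene residual standard deviation (log-expression units).
    ctc_latent_sd : sd of the latent PCL-likeness factor (log-odds units)
        in the background (non-PCL-like) population.
    ctc_intercept, ctc_burden_weight, ctc_noise_sd : the CTC model
        logit(CTC) = intercept + L + w_b * logit(burden) + noise.
    burden_alpha, burden_beta : Beta shape parameters of the burden fraction
        (defaults give median ~0.31, matching typical NDMM plasmacytosis).
    ppcl_ctc_cutoff : CTC fraction at/above which a sample is labeled pPCL.
    ppcl_frac, ppcl_latent_shift, ppcl_latent_sd : a minority PCL-like
        subpopulation whose latent factor is Normal(shift, sd) instead of
        Normal(0, ctc_latent_sd); membership is the ground-truth PCL-like
        flag and drives the survival hazard.  Defaults place the
        subpopulation's median CTC near 30% while the background exceeds
        the 20% cutoff only ~2% of the time.
    hr_pfs, hr_os : hazard ratios for PCL-like status per endpoint.
    median_pfs_months, median_os_months : baseline (non-PCL-like) medians.
    censor_rate : target fraction censored under uniform censoring.
    platform_shift_sd, platform_scale_sd, platform_noise_sd : per-gene
        affine distortion parameters for the cross-platform re-measurement.
    detection_limit : CTC fractions below this are flagged undetectable.
    seed : master seed; all per-cohort stages derive their streams from it.
    gene_param_seed : seed for per-gene truth parameters (baseline mean
        expression); deliberately separate from ``seed`` so cohorts drawn
        from the same generative process share the same gene panel, as a
        discovery/validation pair measured with one pipeline would.
    """

    n_samples: int = 110
    n_genes: int = 2000
    n_signal_genes: int = 100
    signal_effect: float = 0.5
    burden_effect: float = 0.5
    n_confounded_genes: int = 100
    noise_sd: float = 1.0
    ctc_latent_sd: float = 2.0
    ctc_intercept: float = -7.0
    ctc_burden_weight: float = 1.5
    ctc_noise_sd: float = 0.5
    burden_alpha: float = 2.0
    burden_beta: float = 4.0
    ppcl_ctc_cutoff: float = 0.20
    ppcl_frac: float = 0.22
    ppcl_latent_shift: float = 7.5
    ppcl_latent_sd: float = 1.5
    hr_pfs: float = 1.85
    hr_os: float = 2.12
    median_pfs_months: float = 30.0
    median_os_months: float = 60.0
    censor_rate: float = 0.3
    platform_shift_sd: float = 0.5
    platform_scale_sd: float = 0.2
    platform_noise_sd: float = 0.3
    detection_limit: float = 1e-5
    seed: int = 0
    gene_param_seed: int = 20220331

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_signal_genes < 0 or self.n_confounded_genes < 0:
            raise ConfigurationError("n_signal_genes/n_confounded_genes must be >= 0")
        if self.n_signal_genes + self.n_confounded_genes > self.n_genes:
            raise ConfigurationError(
                "n_signal_genes + n_confounded_genes exceeds n_genes"
            )
        for name in ("noise_sd", "ctc_latent_sd", "ctc_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("burden_alpha", "burden_beta"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("ppcl_ctc_cutoff", "ppcl_frac", "censor_rate",
                     "detection_limit"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.ppcl_latent_sd <= 0:
            raise ConfigurationError("ppcl_latent_sd must be > 0")
        for name in ("hr_pfs", "hr_os"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("platform_shift_sd", "platform_scale_sd", "platform_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """One generated cohort plus its ground truth."""

    expression: ExpressionMatrix
    annotation: pd.DataFrame      # indexed by sample_id
    survival: pd.DataFrame        # long format, one row per sample x endpoint
    truth_genes: pd.Series        # gene_id -> {signal, confounded, null}
    truth_latent: pd.Series       # sample_id -> latent PCL-likeness factor
    truth_pcl_like: pd.Series     # sample_id -> bool
    config: SimulationConfig


def _censor_horizon(rate: float, censor_rate: float) -> float:
    """Uniform-censoring horizon c so that P(C < T) = censor_rate when
    T ~ Exp(rate), C ~ U(0, c): solves (1 - exp(-x))/x = censor_rate."""
    if censor_rate <= 0:
        return math.inf
    f = lambda x: (1.0 - math.exp(-x)) / x - censor_rate
    x = optimize.brentq(f, 1e-9, 1e6)
    return x / rate


def generate_cohort(config: SimulationConfig, *, study_id: str = "S1") -> SyntheticCohort:
    """Generate one cohort; byte-identical output for identical configs."""
    config.validate()
    rng = np.random.default_rng(int(config.seed) + STAGE_SEED_EXPRESSION)

    n, g = config.n_samples, config.n_genes
    sample_ids = pd.Index([f"{study_id}_{i:04d}" for i in range(n)], name="sample_id")
    gene_ids = pd.Index([f"G{j:06d}" for j in range(g)], name="gene_id")

    pcl_like = rng.random(n) < config.ppcl_frac
    latent = np.where(
        pcl_like,
        rng.normal(config.ppcl_latent_shift, config.ppcl_latent_sd, size=n),
        rng.normal(0.0, config.ctc_latent_sd, size=n),
    )
    burden = rng.beta(config.burden_alpha, config.burden_beta, size=n)
    logit_ctc = (
        config.ctc_intercept
        + latent
        + config.ctc_burden_weight * logit(burden)
        + rng.normal(0.0, config.ctc_noise_sd, size=n)
    )
    ctc = 1.0 / (1.0 + np.exp(-logit_ctc))

    roles = np.array(
        ["signal"] * config.n_signal_genes
        + ["confounded"] * config.n_confounded_genes
        + ["null"] * (g - config.n_signal_genes - config.n_confounded_genes)
    )
    grng = np.random.default_rng(int(config.gene_param_seed))
    baseline = grng.normal(6.0, 1.5, size=g)
    expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n))
    sig = roles == "signal"
    con = roles == "confounded"
    expr[sig] += config.signal_effect * latent[None, :]
    expr[con] += config.burden_effect * logit(burden)[None, :]

    label = np.where(ctc >= config.ppcl_ctc_cutoff, "pPCL", "NDMM")
    detectable = ctc >= config.detection_limit

    annotation = pd.DataFrame(
        {
            "ctc_fraction": ctc,
            "ctc_detectable": detectable,
            "burden_fraction": burden,
            "disease_label": label,
            "study_id": study_id,
            "age_le_65": rng.random(n) < 0.5,
        },
        index=sample_ids,
    )

    srng = np.random.default_rng(int(config.seed) + STAGE_SEED_SURVIVAL)
    rows = []
    for endpoint, hr, median in (
        ("PFS", config.hr_pfs, config.median_pfs_months),
        ("OS", config.hr_os, config.median_os_months),
    ):
        lam0 = math.log(2.0) / median
        rate = lam0 * np.where(pcl_like, hr, 1.0)
        t = srng.exponential(1.0 / rate)
        horizon = _censor_horizon(lam0, config.censor_rate)
        c = srng.uniform(0.0, horizon, size=n) if math.isfinite(horizon) else np.full(n, np.inf)
        time = np.minimum(t, c)
        rows.append(pd.DataFrame({
            "sample_id": sample_ids,
            "study_id": study_id,
            "time": np.maximum(time, 1e-6),
            "event": (t <= c).astype(int),
            "endpoint": endpoint,
            "pcl_like": pcl_like,
            "age_le_65": annotation["age_le_65"].to_numpy(),
        }))
    survival = pd.concat(rows, ignore_index=True)

    return SyntheticCohort(
        expression=ExpressionMatrix(gene_ids, sample_ids, expr, "synthetic"),
        annotation=annotation,
        survival=survival,
        truth_genes=pd.Series(roles, index=gene_ids, name="role"),
        truth_latent=pd.Series(latent, index=sample_ids, name="latent"),
        truth_pcl_like=pd.Series(pcl_like, index=sample_ids, name="pcl_like"),
        config=config,
    )


def generate_multistudy(config: SimulationConfig, n_studies: int,
                        per_study_n: int) -> list[SyntheticCohort]:
    """Independent cohorts sharing truth parameters; study i uses seed
    ``master_seed + 1000 * (i + 1)`` and sample-id prefix ``S{i+1}``."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    cohorts = []
    for i in range(n_studies):
        cfg = SimulationConfig(**{**config.to_dict(),
                                  "n_samples": per_study_n,
                                  "seed": int(config.seed) + 1000 * (i + 1)})
        cohorts.append(generate_cohort(cfg, study_id=f"S{i + 1}"))
    return cohorts


def apply_platform_distortion(cohort: SyntheticCohort,
                              config: SimulationConfig | None = None) -> ExpressionMatrix:
    """Re-measure the cohort's expression on a second platform.

    Each gene g is transformed a_g + c_g * x + noise with
    a_g ~ Normal(0, platform_shift_sd), c_g ~ LogNormal(0, platform_scale_sd)
    (so c_g > 0), and independent Normal(0, platform_noise_sd) noise —
    emulating paired microarray/RNA-seq profiles of the same samples.
    """
    config = config or cohort.config
    config.validate()
    rng = np.random.default_rng(int(config.seed) + STAGE_SEED_PLATFORM)
    g, n = cohort.expression.values.shape
    shift = rng.normal(0.0, config.platform_shift_sd, size=g) \
        if config.platform_shift_sd > 0 else np.zeros(g)
    scale = rng.lognormal(0.0, config.platform_scale_sd, size=g) \
        if config.platform_scale_sd > 0 else np.ones(g)
    noise = rng.normal(0.0, config.platform_noise_sd, size=(g, n)) \
        if config.platform_noise_sd > 0 else 0.0
    values = shift[:, None] + scale[:, None] * cohort.expression.values + noise
    return ExpressionMatrix(cohort.expression.gene_ids,
                            cohort.expression.sample_ids, values, "rnaseq")


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write expression (TSV), annotation/survival/truth (CSV) to a directory."""
    from .io import write_expression

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, outdir / "expression.tsv")
    cohort.annotation.to_csv(outdir / "annotation.csv")
    cohort.survival.to_csv(outdir / "survival.csv", index=False)
    truth = pd.DataFrame({"role": cohort.truth_genes})
    truth.to_csv(outdir / "truth_genes.csv")
    pd.DataFrame({"latent": cohort.truth_latent,
                  "pcl_like": cohort.truth_pcl_like}).to_csv(
        outdir / "truth_samples.csv")
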