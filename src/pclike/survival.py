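"""Prognostic evaluation of PCL-like status.

Kaplan-Meier curves with the k-group log-rank test, Cox proportional-hazards
models stratified by study (Breslow tie handling, Wald confidence intervals)
via lifelines, and DerSimonian-Laird random-effects meta-analysis of
per-study log hazard ratios.

Endpoints follow the usual definitions: a progression-free-survival event is
progressive disease or death from any cause; an overall-survival event is
death from any cause.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "MetaResult",
    "COMPOSITE_SEPARATOR",
    "km_logrank",
    "cox_fit",
    "random_effects_meta",
]

#: separator used to build composite Kaplan-Meier groups (e.g. R-ISS x PCL-like)
COMPOSITE_SEPARATOR = " / "


@dataclass
class MetaResult:
    """Per-study and pooled hazard-ratio summary (random effects)."""

    per_study: pd.DataFrame      # study_id, log_hr, se, n, n_events
    pooled_log_hr: float
    pooled_ci_95: tuple[float, float]
    tau2: float
    method: str = "DerSimonian-Laird"

    @property
    def pooled_hr(self) -> float:
        return float(np.exp(self.pooled_log_hr))

    @property
    def pooled_hr_ci_95(self) -> tuple[float, float]:
        lo, hi = self.pooled_ci_95
        return float(np.exp(lo)), float(np.exp(hi))


def _group_key(records: pd.DataFrame, group_by) -> pd.Series:
    if isinstance(group_by, str):
        return records[group_by].astype(str)
    parts = [records[c].astype(str) for c in group_by]
    out = parts[0]
    for p in parts[1:]:
        out = out.str.cat(p, sep=COMPOSITE_SEPARATOR)
    return out


def km_logrank(records: pd.DataFrame, group_by="pcl_like"):
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    ``group_by`` is a column name or a list of columns (composite groups are
    level strings joined by ``COMPOSITE_SEPARATOR``).  Returns
    ``(curves, chi2, df, p)`` where curves maps group label to the
    product-limit survival table (columns: timeline, survival, at_risk).
    """
    req = {"time", "event"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must contain columns {sorted(req)}")
    if (records["time"] <= 0).any():
        raise ValueError("all times must be > 0")
    groups = _group_key(records, group_by)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("log-rank needs at least 2 non-empty groups")

    curves = {}
    for lev in levels:
        mask = (groups == lev).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(records.loc[mask, "time"], records.loc[mask, "event"],
                label=str(lev))
        tab = kmf.event_table
        curves[str(lev)] = pd.DataFrame({
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].reindex(
                kmf.survival_function_.index).to_numpy(),
        })
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return curves, float(res.test_statistic), int(len(levels) - 1), float(res.p_value)


def cox_fit(records: pd.DataFrame, covariate_set=("pcl_like", "age_le_65"),
            strata: str | None = "study_id") -> pd.DataFrame:
    """Cox proportional-hazards fit, baseline hazard stratified by study.

    Partial-likelihood estimates with Breslow tie handling (lifelines'
    method) and per-covariate Wald 95% confidence intervals and p-values.
    Returns a DataFrame indexed by covariate with columns hr, ci_lower,
    ci_upper, log_hr, se, p, n, n_events.
    """
    covariate_set = list(covariate_set)
    cols = ["time", "event"] + covariate_set + ([strata] if strata else [])
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records missing column {missing[0]!r}")
    df = records[cols].dropna().copy()
    for c in covariate_set:
        df[c] = pd.to_numeric(df[c].astype(float) if df[c].dtype != object
                              else df[c])
    for c in covariate_set:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    if strata:
        ev = df.groupby(strata)["event"].sum()
        dead = ev[ev == 0]
        if len(dead):
            raise ValueError(f"stratum {dead.index[0]!r} has no events")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                strata=[strata] if strata else None)
    except ConvergenceError as exc:
        raise ValueError(
            f"Cox fit failed to converge (possible monotone likelihood / "
            f"perfect separation) for covariates {covariate_set}: {exc}"
        ) from exc
    summ = cph.summary
    out = pd.DataFrame({
        "hr": summ["exp(coef)"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "log_hr": summ["coef"],
        "se": summ["se(coef)"],
        "p": summ["p"],
    })
    out["n"] = len(df)
    out["n_events"] = int(df["event"].sum())
    out.index.name = "covariate"
    return out


def random_effects_meta(per_study_log_hr, per_study_se,
                        study_ids=None, n=None, n_events=None) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-study log hazard ratios.

    With fixed-effect weights w_i = 1/se_i^2 and Cochran's
    Q = sum w_i (theta_i - theta_fe)^2, the between-study variance is
    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w)); the pooled
    estimate uses w*_i = 1/(se_i^2 + tau^2) with a normal-approximation 95%
    confidence interval.
    """
    theta = np.asarray(per_study_log_hr, dtype=float)
    se = np.asarray(per_study_se, dtype=float)
    k = theta.size
    if k == 0:
        raise ValueError("meta-analysis needs at least 1 study")
    if se.shape != theta.shape or np.any(se <= 0):
        raise ValueError("per_study_se must be positive and aligned")

    w = 1.0 / se ** 2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    if k == 1:
        tau2 = 0.0
    else:
        q = float(np.sum(w * (theta - theta_fe) ** 2))
        denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se ** 2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    zcrit = float(stats.norm.ppf(0.975))
    ci = (pooled - zcrit * pooled_se, pooled + zcrit * pooled_se)

    per_study = pd.DataFrame({
        "study_id": study_ids if study_ids is not None else [f"study_{i+1}" for i in range(k)],
        "log_hr": theta,
        "se": se,
        "n": n if n is not None else np.full(k, np.nan),
        "n_events": n_events if n_events is not None else np.full(k, np.nan),
    })
    return MetaResult(per_study=per_study, pooled_log_hr=pooled,
                      pooled_ci_95=ci, tau2=tau2)
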