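"""Burden-stratified overall-survival analysis.

Patients are grouped by somatic mtDNA mutational burden either as
mutation-negative vs mutation-positive (``any_vs_none``) or below/above
the cohort mean burden rounded to the nearest integer (``mean_split``,
with burden <= threshold -> low).  Overall survival is summarised with the
Kaplan-Meier product-limit estimator, compared with the log-rank test and
modelled with a Cox proportional-hazards fit (Efron tie handling, Wald
confidence intervals), optionally adjusted for covariates such as age,
tumor stage, clinical stage and hormone-receptor status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .errors import InputError, NonEstimableError
from .summary import CohortTable

logger = logging.getLogger(__name__)

ANY_VS_NONE = "any_vs_none"
MEAN_SPLIT = "mean_split"


@dataclass(frozen=True)
class BurdenStrata:
    """Burden-grouping rule; ``threshold`` is derived for mean_split."""

    rule: str = ANY_VS_NONE
    threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rule not in (ANY_VS_NONE, MEAN_SPLIT):
            raise InputError(f"unknown stratification rule {self.rule!r}")


SURVIVAL_COLUMNS = ["patient_id", "time", "event", "burden", "group"]


def stratify(cohort: CohortTable, rule: Optional[BurdenStrata] = None) -> pd.DataFrame:
    """Build per-patient survival records with burden groups.

    Requires ``follow_up_months`` and ``vital_status`` (``death`` /
    ``censored``) in the cohort metadata; patients with missing survival
    fields are excluded with a log entry.
    """
    rule = rule or BurdenStrata()
    meta = cohort.patients.copy()
    for col in ("follow_up_months", "vital_status"):
        if col not in meta.columns:
            raise InputError(f"metadata lacks {col!r}")
    burden = cohort.somatic_burden()
    meta["patient_id"] = meta["patient_id"].astype(str)
    meta["burden"] = meta["patient_id"].map(burden).fillna(0).astype(int)
    ok = meta["follow_up_months"].notna() & meta["vital_status"].notna()
    ok &= pd.to_numeric(meta["follow_up_months"], errors="coerce") > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("stratify: excluded %d patients with missing survival fields", n_dropped)
    meta = meta[ok]

    if rule.rule == ANY_VS_NONE:
        group = np.where(meta["burden"] > 0, "positive", "negative")
        threshold = 0
    else:
        threshold = (
            rule.threshold
            if rule.threshold is not None
            else int(round(float(meta["burden"].mean())))
        )
        group = np.where(meta["burden"] <= threshold, "low", "high")

    out = pd.DataFrame(
        {
            "patient_id": meta["patient_id"],
            "time": pd.to_numeric(meta["follow_up_months"]),
            "event": (meta["vital_status"] == "death").astype(int),
            "burden": meta["burden"],
            "group": group,
        }
    ).reset_index(drop=True)
    out.attrs["threshold"] = threshold
    return out


def km_curve(records: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Product-limit survival function per group.

    Returns, per group, a DataFrame with ``time``, ``survival``, ``at_risk``
    and ``events`` columns; censored subjects leave the risk set without a
    step.  An all-censored group yields a flat curve at 1.0.
    """
    out: Dict[str, pd.DataFrame] = {}
    for group, grp in records.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(group))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[str(group)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "survival": surv.reindex(table.index).to_numpy(dtype=float),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
                "events": table["observed"].to_numpy(dtype=int),
            }
        ).reset_index(drop=True)
    return out


def logrank(records: pd.DataFrame) -> tuple:
    """Two-group log-rank test; returns (statistic, p_value)."""
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise NonEstimableError(f"log-rank needs exactly 2 groups, got {groups}")
    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    res = _lifelines_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    covariates: tuple = ()


def hazard_ratio(
    records: pd.DataFrame, covariates: Sequence[str] = ()
) -> HazardRatioResult:
    """Cox proportional-hazards HR of the high-risk group with Wald 95% CI.

    The group indicator is 1 for the ``positive``/``high`` label.  Efron's
    approximation handles tied event times.  Raises
    :class:`NonEstimableError` with no events, a single group, or a
    degenerate (separated) fit.
    """
    df = records.copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise NonEstimableError("hazard ratio needs two groups")
    high_label = "positive" if "positive" in groups else "high"
    df["group_indicator"] = (df["group"] == high_label).astype(int)
    if df["event"].sum() == 0:
        raise NonEstimableError("no events observed")
    cols = ["time", "event", "group_indicator", *covariates]
    cph = CoxPHFitter()
    try:
        cph.fit(df[cols], duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise NonEstimableError(f"Cox fit failed: {exc}") from exc
    coef = float(cph.params_["group_indicator"])
    se = float(cph.standard_errors_["group_indicator"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 100:
        raise NonEstimableError("Cox fit degenerate (separation?)")
    z = 1.959963984540054
    return HazardRatioResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=float(cph.summary.loc["group_indicator", "p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=tuple(covariates),
    )
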