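"""Fold-change stratification, Kaplan-Meier / log-rank survival analysis,
and the threshold differential-expression filter.

Patients are stratified by their tumor/normal expression ratio for a single
feature (boundary inclusive: a ratio exactly at the threshold counts as
upregulated).  Survival curves use the product-limit estimator and group
differences the standard two-group log-rank test, both via lifelines.
``event = 1`` means the death was observed; 0 means right-censored.

The DE filter applies a Welch t test per gene on log2(x + 1) values with
Benjamini-Hochberg adjustment; its pass thresholds are strict inequalities
(adjusted p < p_threshold and |log2FC| > lfc_threshold), so a gene sitting
exactly on a boundary fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError, logger


@dataclass
class SurvivalRecord:
    """One patient's time-to-event and fold-change stratum."""

    patient_id: str
    time: float
    event: int
    stratum: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"{self.patient_id}: negative survival time")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.patient_id}: event must be 0 or 1")
        if self.stratum not in ("upregulated", "other"):
            raise ValidationError(f"{self.patient_id}: bad stratum {self.stratum!r}")


@dataclass
class DeResult:
    """Per-gene differential-expression test result."""

    gene_id: str
    log2_fold_change: float
    p: float
    p_adjusted: float
    passes: bool


def stratify_by_fold_change(
    survival: pd.DataFrame, threshold: float = 2.0
) -> tuple[list[SurvivalRecord], list[str]]:
    """Assign each patient a stratum from the tumor/normal ratio.

    ``survival`` needs columns patient_id, time, event, tumor_expr,
    normal_expr.  fold_change = tumor/normal; patients at or above the
    threshold are ``upregulated`` (the boundary is inclusive).  Patients
    with normal expression 0 are unevaluable and returned separately with a
    warning.
    """
    required = {"patient_id", "time", "event", "tumor_expr", "normal_expr"}
    missing = required - set(survival.columns)
    if missing:
        raise ValidationError(f"survival table missing columns {sorted(missing)}")
    records, excluded = [], []
    for row in survival.itertuples(index=False):
        if row.normal_expr <= 0:
            logger.warning(
                "patient %s has normal expression %s; excluded from stratification",
                row.patient_id,
                row.normal_expr,
            )
            excluded.append(str(row.patient_id))
            continue
        fold = float(row.tumor_expr) / float(row.normal_expr)
        records.append(
            SurvivalRecord(
                patient_id=str(row.patient_id),
                time=float(row.time),
                event=int(row.event),
                stratum="upregulated" if fold >= threshold else "other",
                fold_change=fold,
            )
        )
    return records, excluded


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate honoring right censoring.

    Returns a step-function table with columns time, at_risk, survival
    (starting at survival 1 at time 0 and non-increasing).
    """
    if not records:
        raise ValidationError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if (times < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    if out.empty or out["time"].iloc[0] > 0:
        out = pd.concat(
            [pd.DataFrame({"time": [0.0], "at_risk": [len(records)], "survival": [1.0]}), out],
            ignore_index=True,
        )
    return out


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value)."""
    if not group_a or not group_b:
        raise ValidationError("both strata must be non-empty")
    res = _lifelines_logrank(
        np.array([r.time for r in group_a], dtype=float),
        np.array([r.time for r in group_b], dtype=float),
        event_observed_A=np.array([r.event for r in group_a], dtype=int),
        event_observed_B=np.array([r.event for r in group_b], dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


def split_records(
    records: list[SurvivalRecord],
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Split stratified records into (upregulated, other)."""
    up = [r for r in records if r.stratum == "upregulated"]
    other = [r for r in records if r.stratum == "other"]
    return up, other


def de_filter(
    expr: pd.DataFrame,
    condition: pd.Series,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    pseudocount: float = 1.0,
) -> list[DeResult]:
    """Threshold differential-expression filter between two conditions.

    ``expr`` is genes x samples on a positive scale; ``condition`` labels
    each sample with one of exactly two values (the lexicographically
    smaller label is the reference; log2FC = mean(other) - mean(reference)
    on log2(x + pseudocount) values).  Per gene: Welch t test, then BH
    adjustment across genes.  A gene passes iff adjusted p < p_threshold
    and |log2FC| > lfc_threshold, both strict.
    """
    levels = sorted(condition.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {levels}")
    ref_samples = condition.index[condition == levels[0]]
    alt_samples = condition.index[condition == levels[1]]
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValidationError("need >= 2 replicates per condition")
    log_ref = np.log2(expr[ref_samples].to_numpy(dtype=float) + pseudocount)
    log_alt = np.log2(expr[alt_samples].to_numpy(dtype=float) + pseudocount)
    lfc = log_alt.mean(axis=1) - log_ref.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(log_alt, log_ref, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # zero variance in both groups: identical values -> no evidence (p=1),
    # distinct constant values -> infinitely strong evidence (p=0)
    nan_mask = np.isnan(pvals)
    pvals[nan_mask & (lfc == 0)] = 1.0
    pvals[nan_mask & (lfc != 0)] = 0.0
    adj = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for gene, fc, p, pa in zip(expr.index, lfc, pvals, adj):
        passes = bool(pa < p_threshold and abs(fc) > lfc_threshold)
        results.append(DeResult(str(gene), float(fc), float(p), float(pa), passes))
    return results


def survival_summary(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Per-stratum KM curves in one tidy table (stratum, time, at_risk, survival)."""
    frames = []
    for name, grp in (("upregulated", split_records(records)[0]), ("other", split_records(records)[1])):
        if not grp:
            continue
        km = km_estimate(grp)
        km.insert(0, "stratum", name)
        frames.append(km)
    return pd.concat(frames, ignore_index=True)


def median_survival(records: list[SurvivalRecord]) -> float:
    """Median survival time from the KM curve (inf if never reached)."""
    km = km_estimate(records)
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if not below.empty else math.inf
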