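"""Cohort-level statistics: the ageing-index-vs-age model and group tests.

The healthy-group relationship is modelled as a straight line
``y_AGI = slope * age + intercept`` fitted by ordinary least squares (the
identity-link Gaussian generalized linear model).  Agreement of individual
subjects with the model is summarized Bland-Altman style as differences
``AGI - y_AGI(age)``; the healthy and patient difference distributions are
compared with Welch's unequal-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .signal_io import CohortRecord


@dataclass(frozen=True)
class RegressionModel:
    """Fitted line AGI = slope * age + intercept."""

    slope: float        # AGI units per year
    intercept: float    # AGI units
    r: float            # Pearson correlation of (age, AGI)
    residual_sd: float  # SD of fit residuals, AGI units

    def predict(self, age) -> np.ndarray | float:
        return self.slope * np.asarray(age, dtype=float) + self.intercept


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test summary."""

    t: float
    df: float
    p_value: float
    mean_healthy: float
    mean_patient: float


def fit_agi_age(records: Sequence[CohortRecord],
                group: str = "healthy") -> RegressionModel:
    """Least-squares fit of AGI on age within one group."""
    sel = [r for r in records if r.group == group]
    if len(sel) < 3:
        raise ConfigError(
            f"need at least 3 records in group {group!r}, got {len(sel)}")
    age = np.array([r.age for r in sel])
    agi = np.array([r.agi for r in sel])
    if np.ptp(age) == 0:
        raise ConfigError("zero age variance: regression is undefined")
    res = stats.linregress(age, agi)
    resid = agi - (res.slope * age + res.intercept)
    return RegressionModel(slope=float(res.slope),
                           intercept=float(res.intercept),
                           r=float(res.rvalue),
                           residual_sd=float(np.std(resid, ddof=1)))


def bland_altman_vs_model(records: Sequence[CohortRecord],
                          model: RegressionModel) -> pd.DataFrame:
    """Per-record differences AGI - model(age), with group labels.

    The returned frame has one row per record (columns ``subject_id``,
    ``group``, ``age``, ``agi``, ``diff``); per-group summaries come from
    :func:`group_summaries`.
    """
    rows = [(r.subject_id, r.group, r.age, r.agi,
             r.agi - float(model.predict(r.age))) for r in records]
    return pd.DataFrame(rows, columns=["subject_id", "group", "age",
                                       "agi", "diff"])


def group_summaries(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the model differences per group.

    The healthy-group SD is the model's dispersion (SD_AGI); the patient
    mean is the systematic offset of the patient group from the model.
    """
    return (diffs.groupby("group")["diff"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
            .reset_index())


def compare_groups(diffs_healthy: Sequence[float],
                   diffs_patient: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-sided."""
    h = np.asarray(diffs_healthy, dtype=float)
    p = np.asarray(diffs_patient, dtype=float)
    if h.size < 2 or p.size < 2:
        raise ConfigError("need at least 2 values per group")
    if np.var(h) == 0 and np.var(p) == 0:
        raise ConfigError("zero variance in both groups: t undefined")
    res = stats.ttest_ind(h, p, equal_var=False)
    vh, vp = np.var(h, ddof=1) / h.size, np.var(p, ddof=1) / p.size
    df = (vh + vp) ** 2 / (vh ** 2 / (h.size - 1) + vp ** 2 / (p.size - 1))
    return GroupComparison(t=float(res.statistic), df=float(df),
                           p_value=float(res.pvalue),
                           mean_healthy=float(h.mean()),
                           mean_patient=float(p.mean()))
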