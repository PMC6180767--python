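"""Kaplan–Meier estimation and log-rank comparison of EFS/OS by stage.

Product-limit curves are computed per stage; fixed-horizon probabilities
(default 24 months for the "2-year" summaries) are read off the step
function. Groups are compared with the asymptotic k-group log-rank test,
with an optional label-permutation p-value for small groups. Ties between
events and censorings at the same time follow the standard convention:
events precede censorings, so subjects censored at an event time remain in
that risk set.

Point estimates only; no confidence bands are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .patient_model import CauseOfDeath, PatientRecord
from .staging import StageAssignment

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "km_fit",
    "survival_at",
    "logrank",
    "summarize_outcomes",
    "DEFAULT_HORIZON_MONTHS",
]

#: Default horizon for "2-year" survival summaries.
DEFAULT_HORIZON_MONTHS: float = 24.0


@dataclass(frozen=True)
class SurvivalCurve:
    """A product-limit estimate with its risk sets.

    Arrays are aligned over the ordered distinct observed times; the
    estimate is the right-continuous step function equal to 1 before the
    first event.
    """

    times: np.ndarray  # distinct observed times, increasing
    at_risk: np.ndarray  # subjects at risk just before each time
    n_events: np.ndarray
    n_censored: np.ndarray
    estimates: np.ndarray  # S(t) at each time


def km_fit(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Fit the Kaplan–Meier product-limit estimator.

    *times* are positive follow-up times; *events* flags an observed event
    (True) versus right-censoring (False). With no censoring the estimate
    equals one minus the empirical CDF of the event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("at least one subject is required")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.drop(index=0.0, errors="ignore")
    est = kmf.survival_function_at_times(table.index.values).to_numpy()
    return SurvivalCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        estimates=est,
    )


def survival_at(curve: SurvivalCurve, t_months: float) -> float:
    """Evaluate the right-continuous survival step function at *t_months*."""
    if t_months <= 0:
        raise ValueError("t_months must be positive")
    idx = np.searchsorted(curve.times, t_months, side="right") - 1
    return 1.0 if idx < 0 else float(curve.estimates[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square
    df: int  # groups - 1
    p_value: float  # asymptotic
    permutation_p_value: float | None = None


def _logrank_statistic(
    times: np.ndarray, events: np.ndarray, labels: np.ndarray
) -> tuple[float, int]:
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), int(res.degrees_of_freedom)


def logrank(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
    n_permutations: int | None = None,
    seed: int | None = None,
) -> LogRankResult:
    """k-group log-rank test on (times, events) per group.

    The p-value is asymptotic chi-square on k−1 degrees of freedom. When
    *n_permutations* is given, a label-permutation p-value (with the +1
    correction) is computed as well — useful when group sizes are small.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    times_list, events_list, labels_list = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError("every group must be non-empty")
        times_list.append(t)
        events_list.append(e)
        labels_list.append(np.full(t.size, g))
    times = np.concatenate(times_list)
    events = np.concatenate(events_list)
    labels = np.concatenate(labels_list)

    stat, df = _logrank_statistic(times, events, labels)
    from scipy.stats import chi2

    p = float(chi2.sf(stat, df))

    perm_p = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            s, _ = _logrank_statistic(times, events, perm)
            if s >= stat:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
    return LogRankResult(statistic=stat, df=df, p_value=p, permutation_p_value=perm_p)


def summarize_outcomes(
    cohort: Sequence[PatientRecord],
    stages: Sequence[StageAssignment],
    horizon: float = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """Per-stage outcome table: n, deaths by cause, and horizon EFS/OS.

    Stages are pooled to their major level (3A/3B → 3). Deaths partition by
    recorded cause; EFS/OS columns are the Kaplan–Meier estimates at the
    horizon (percent).
    """
    if len(cohort) != len(stages):
        raise ValueError("one stage assignment per patient is required")
    frame = pd.DataFrame(
        {
            "stage": [s.stage.pooled for s in stages],
            "efs_time": [p.outcome.efs_time_months for p in cohort],
            "efs_event": [p.outcome.efs_event for p in cohort],
            "os_time": [p.outcome.os_time_months for p in cohort],
            "os_event": [p.outcome.os_event for p in cohort],
            "cause": [p.outcome.cause_of_death for p in cohort],
        }
    )
    rows = []
    for stage, grp in frame.groupby("stage", sort=True):
        deaths = int(grp["os_event"].sum())
        causes = {
            f"deaths_{c.value}": int((grp.loc[grp["os_event"], "cause"] == c).sum())
            for c in CauseOfDeath
            if c is not CauseOfDeath.NOT_APPLICABLE
        }
        efs = survival_at(km_fit(grp["efs_time"], grp["efs_event"]), horizon)
        os_ = survival_at(km_fit(grp["os_time"], grp["os_event"]), horizon)
        rows.append(
            {
                "stage": stage,
                "n": len(grp),
                "deaths": deaths,
                **causes,
                f"efs_{horizon:g}mo_pct": 100 * efs,
                f"os_{horizon:g}mo_pct": 100 * os_,
            }
        )
    return pd.DataFrame(rows).set_index("stage")
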