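"""Patient stratification by miRNA expression and survival comparison.

Patients are split into two groups by K-means (K=2) on the expression
of the miRNAs linked to a drug, and the groups are compared with the
two-sample log-rank test; Kaplan–Meier curves summarise each group.
The "good prognosis" group is the one with the higher Kaplan–Meier
survival at the last time both curves cover — cluster indices carry no
meaning on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.cluster import KMeans

__all__ = [
    "SurvivalCohort",
    "StratificationResult",
    "kmeans2",
    "logrank",
    "km_curve",
    "group_fold_change",
    "stratify",
]


@dataclass
class SurvivalCohort:
    """Follow-up times, event indicators and miRNA expression."""

    time: pd.Series  # indexed by patient id
    event: pd.Series  # 1 = death observed, 0 = censored
    mirna_expr: pd.DataFrame  # patients x miRNAs

    def __post_init__(self) -> None:
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event must index the same patients")
        self.mirna_expr = self.mirna_expr.reindex(self.time.index)
        if self.mirna_expr.isna().any().any():
            raise ValueError("missing expression values after alignment")

    @property
    def patients(self) -> pd.Index:
        return self.time.index


@dataclass
class StratificationResult:
    """Two-group stratification with its survival comparison."""

    labels: pd.Series  # "good" / "poor" per patient
    statistic: float
    p_value: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    fold_change: pd.Series | None = None  # good-group mean / poor-group mean


def preprocess_expression(expr: pd.DataFrame, raw: bool = False) -> pd.DataFrame:
    """log2(x+1) then per-miRNA z-score, unless ``raw`` is requested."""
    if raw:
        return expr
    logged = np.log2(expr + 1.0)
    sd = logged.std(ddof=0).replace(0, 1.0)
    return (logged - logged.mean()) / sd


def kmeans2(
    expr_submatrix: pd.DataFrame, seed: int = 0, n_restarts: int = 10
) -> pd.Series:
    """2-means clustering of patients, best of ``n_restarts`` starts.

    Deterministic under ``seed``; degenerate input (all rows identical)
    is an error since no two-group structure exists.
    """
    x = expr_submatrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 patients to cluster")
    if np.allclose(x, x[0]):
        raise ValueError("all patients identical: clustering is degenerate")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return pd.Series(labels, index=expr_submatrix.index, name="group")


def logrank(
    time: pd.Series, event: pd.Series, labels: pd.Series
) -> tuple[float, float]:
    """Two-group log-rank test (1 df chi-square).

    Returns (statistic, p).  With no observed events in either group the
    comparison is undefined and (nan, nan) is returned.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two non-empty groups")
    mask = labels == groups[0]
    if event.sum() == 0:
        return float("nan"), float("nan")
    res = logrank_test(
        time[mask], time[~mask], event_observed_A=event[mask], event_observed_B=event[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(times: pd.Series, events: pd.Series) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a step table.

    Columns: time, survival.  Starts at S(0)=1 and is non-increasing;
    right-censored observations leave the curve flat.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def _survival_at(curve: pd.DataFrame, t: float) -> float:
    below = curve[curve["time"] <= t]
    return float(below["survival"].iloc[-1]) if len(below) else 1.0


def _restricted_mean(curve: pd.DataFrame, tau: float) -> float:
    """Area under the KM step function on [0, tau]."""
    times = curve["time"].to_numpy(dtype=float)
    surv = curve["survival"].to_numpy(dtype=float)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(times, surv):
        if t > tau:
            break
        area += prev_s * (min(t, tau) - prev_t)
        prev_t, prev_s = t, s
    area += prev_s * max(tau - prev_t, 0.0)
    return area


def group_fold_change(expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Per-miRNA ratio of group means: label "good" over label "poor".

    A zero poor-group mean leaves that miRNA's ratio as inf/nan, which
    callers should treat as flagged.
    """
    good = expr.loc[labels[labels == "good"].index].mean()
    poor = expr.loc[labels[labels == "poor"].index].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        return good / poor


def stratify(
    cohort: SurvivalCohort,
    mirnas: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    raw: bool = False,
) -> StratificationResult:
    """K-means(2) stratification on selected miRNAs + log-rank comparison.

    Expression is log2(x+1)-transformed and z-scored per miRNA before
    clustering (``raw=True`` skips this); fold changes are reported on
    the raw scale.  Groups are renamed good/poor by Kaplan–Meier
    ordering (restricted mean survival over the common follow-up span).
    """
    expr = cohort.mirna_expr if mirnas is None else cohort.mirna_expr[mirnas]
    clusters = kmeans2(preprocess_expression(expr, raw=raw), seed=seed, n_restarts=n_restarts)
    curves = {}
    for g in (0, 1):
        idx = clusters[clusters == g].index
        curves[g] = km_curve(cohort.time[idx], cohort.event[idx])
    # rank groups by restricted mean survival up to the last common
    # follow-up time: a whole-curve ordering is stable where a single
    # tail point (both curves near zero) is not
    last_common = min(curves[0]["time"].max(), curves[1]["time"].max())
    s0 = _restricted_mean(curves[0], last_common)
    s1 = _restricted_mean(curves[1], last_common)
    good_cluster = 0 if s0 >= s1 else 1
    labels = clusters.map(lambda g: "good" if g == good_cluster else "poor")
    stat, p = logrank(cohort.time, cohort.event, labels)
    return StratificationResult(
        labels=labels,
        statistic=stat,
        p_value=p,
        km_curves={"good": curves[good_cluster], "poor": curves[1 - good_cluster]},
        fold_change=group_fold_change(expr, labels),
    )
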