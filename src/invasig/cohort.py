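"""Cohort stratification by signature-gene outlier expression and
association with clinical categories and survival.

A patient is signature-positive when any signature gene's expression
z-score (relative to the whole cohort) exceeds 3 standard deviations.
The two groups are compared on categorical clinical variables with a
Pearson chi-squared test (no continuity correction) and on overall and
relapse-free survival with Kaplan-Meier curves and the two-group
log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from invasig.signatures import GeneSignature

__all__ = [
    "StratConfig",
    "AssociationResult",
    "SurvivalComparison",
    "stratify",
    "chi_squared",
    "km_estimate",
    "logrank",
    "cohort_report",
]

Z_PREFIX = "z_"


@dataclass
class StratConfig:
    z_threshold: float = 3.0
    direction: str = "above_only"  # or "two_sided"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.direction not in ("above_only", "two_sided"):
            raise ValueError("direction must be 'above_only' or 'two_sided'")


def stratify(cohort: pd.DataFrame, sig: GeneSignature, cfg: StratConfig | None = None) -> pd.Series:
    """Per-patient label: "+" iff any signature gene crosses the z threshold.

    ``above_only`` uses z > threshold; ``two_sided`` uses |z| > threshold.
    The comparison is strict, so z exactly at the threshold is "-".
    """
    cfg = cfg or StratConfig()
    cols = [f"{Z_PREFIX}{g}" for g in sig.genes if f"{Z_PREFIX}{g}" in cohort.columns]
    if not cols:
        raise ValueError("no signature genes present in the cohort table")
    z = cohort[cols].to_numpy(float)
    if cfg.direction == "two_sided":
        z = np.abs(z)
    plus = (z > cfg.z_threshold).any(axis=1)
    return pd.Series(np.where(plus, "+", "-"), index=cohort.index, name="group")


@dataclass(frozen=True)
class AssociationResult:
    table: pd.DataFrame  # group x category counts
    chi2: float
    df: int
    p: float


def chi_squared(contingency: pd.DataFrame) -> AssociationResult:
    """Pearson chi-squared on a count table, no continuity correction."""
    table = pd.DataFrame(contingency)
    obs = table.to_numpy(float)
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return AssociationResult(table=table, chi2=float(chi2), df=int(df), p=float(p))


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step table (time, at_risk, events, survival); censored
    subjects leave the risk set without an event step.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("need at least one observation")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev = kmf.event_table
    out = pd.DataFrame({
        "time": ev.index.to_numpy(float),
        "at_risk": ev["at_risk"].to_numpy(int),
        "events": ev["observed"].to_numpy(int),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(float),
    })
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class SurvivalComparison:
    km_by_group: dict  # group label -> KM step table
    statistic: float
    p: float


def logrank(times, events, groups) -> SurvivalComparison:
    """Two-group log-rank test with per-group KM curves."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank comparison needs exactly 2 groups")
    for lab in labels:
        if t[g == lab].sum() == 0:
            raise ValueError(f"group {lab!r} has no observed risk time")
    res = logrank_test(t[g == labels[0]], t[g == labels[1]],
                       event_observed_A=e[g == labels[0]],
                       event_observed_B=e[g == labels[1]])
    km = {str(lab): km_estimate(t[g == lab], e[g == lab]) for lab in labels}
    return SurvivalComparison(km_by_group=km, statistic=float(res.test_statistic),
                              p=float(res.p_value))


@dataclass(frozen=True)
class CohortReport:
    groups: pd.Series
    associations: dict = field(default_factory=dict)   # variable -> AssociationResult
    survival: dict = field(default_factory=dict)       # endpoint -> SurvivalComparison


_CATEGORICALS = ("subtype", "grade", "vital_status")
_ENDPOINTS = {"os": ("os_time", "os_event"), "rfs": ("rfs_time", "rfs_event")}


def cohort_report(
    cohort: pd.DataFrame, sig: GeneSignature, cfg: StratConfig | None = None
) -> CohortReport:
    """Stratify, then test every clinical association and both endpoints."""
    groups = stratify(cohort, sig, cfg)
    associations = {}
    for var in _CATEGORICALS:
        if var not in cohort.columns:
            continue
        if cohort[var].nunique() < 2:
            raise ValueError(f"clinical variable {var!r} has a single category")
        table = pd.crosstab(groups, cohort[var])
        associations[var] = chi_squared(table)
    survival = {}
    for name, (tcol, ecol) in _ENDPOINTS.items():
        if tcol in cohort.columns and ecol in cohort.columns:
            survival[name] = logrank(cohort[tcol], cohort[ecol], groups)
    return CohortReport(groups=groups, associations=associations, survival=survival)
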