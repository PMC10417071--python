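"""Trial-level statistics: design-stage power, survival, group comparisons.

The design calculation reproduces the study's one-sample weight-change
endpoint: the smallest number of evaluable patients for which a
one-sample t-test (exact noncentral-t power) detects a mean weight
change of -3% against the historical -5% with SD 5%, one-sided alpha
0.025 and power 0.80, followed by inflation for dropout.  Survival uses
the Kaplan-Meier product-limit estimator; between-arm comparisons use
one-way ANOVA for continuous outcomes and the Pearson chi-square test
(no continuity correction) for categorical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import PatientRecord, ValidationError, cohort_to_frame

__all__ = [
    "PowerSpec",
    "SurvivalEstimate",
    "GroupComparison",
    "one_sample_t_power",
    "required_sample_size",
    "normal_approx_sample_size",
    "planned_enrollment",
    "km_estimate",
    "survival_at",
    "compare_groups",
    "nutrition_summary",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the one-sample weight-change test."""

    null_mean: float = -5.0
    alt_mean: float = -3.0
    sd: float = 5.0
    alpha_one_sided: float = 0.025
    power: float = 0.80
    dropout_rate: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.alpha_one_sided < 0.5:
            raise ValidationError("alpha_one_sided must be in (0, 0.5)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if self.sd <= 0:
            raise ValidationError("sd must be positive")
        if self.null_mean == self.alt_mean:
            raise ValidationError("null and alternative means must differ")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")

    @property
    def effect_size(self) -> float:
        return abs(self.alt_mean - self.null_mean) / self.sd


def one_sample_t_power(n: int, effect_size: float, alpha_one_sided: float) -> float:
    """Exact power of the one-sided one-sample t-test at sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    crit = stats.t.ppf(1.0 - alpha_one_sided, df)
    ncp = math.sqrt(n) * effect_size
    return float(1.0 - stats.nct.cdf(crit, df, ncp))


def required_sample_size(spec: PowerSpec, max_n: int = 100_000) -> int:
    """Smallest n whose exact noncentral-t power reaches ``spec.power``."""
    d = spec.effect_size
    for n in range(2, max_n + 1):
        if one_sample_t_power(n, d, spec.alpha_one_sided) >= spec.power:
            return n
    raise ValidationError("no sample size up to max_n attains the power")


def normal_approx_sample_size(spec: PowerSpec) -> int:
    """Closed-form normal-approximation cross-check: ((z_a + z_b) / d)^2."""
    z = stats.norm.ppf
    n = ((z(1 - spec.alpha_one_sided) + z(spec.power)) / spec.effect_size) ** 2
    return math.ceil(n)


def planned_enrollment(n: int, dropout_rate: float) -> int:
    """Inflate the evaluable sample size for the expected dropout."""
    if not 0 <= dropout_rate < 1:
        raise ValidationError("dropout_rate must be in [0, 1)")
    return math.ceil(n / (1.0 - dropout_rate))


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class SurvivalEstimate:
    """Kaplan-Meier product-limit estimate at the distinct observed times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.event_times) == len(self.survival_probs)
                == len(self.at_risk) == len(self.events)):
            raise ValidationError("survival estimate arrays must align")
        if np.any(np.diff(self.survival_probs) > 1e-12):
            raise ValidationError("survival_probs must be non-increasing")


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalEstimate:
    """Product-limit estimator; events at tied times precede censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(times < 0):
        raise ValidationError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[grid, kmf._label].to_numpy()
    return SurvivalEstimate(
        event_times=grid,
        survival_probs=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def survival_at(est: SurvivalEstimate, t: float) -> float:
    """Right-continuous step evaluation of the estimate; S(0) = 1."""
    if t < 0:
        raise ValidationError("t must be non-negative")
    idx = np.searchsorted(est.event_times, t, side="right")
    if idx == 0:
        return 1.0
    return float(est.survival_probs[idx - 1])


# ---------------------------------------------------------------------------
# Group comparisons and the per-arm summary table


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    statistic_value: float
    degrees_of_freedom: tuple
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0, 1]")


def compare_groups(cohort: Sequence[PatientRecord], variable: str,
                   kind: str) -> GroupComparison:
    """Between-arm test: Pearson chi-square or one-way (classical) ANOVA.

    Categories unobserved in every arm are dropped from the contingency
    table before testing.
    """
    frame = cohort_to_frame(cohort)
    if variable not in frame.columns:
        raise ValidationError(f"variable {variable!r} not found in cohort")
    arms = frame["arm_label"].unique()
    if len(arms) < 2:
        raise ValidationError("need at least two arms to compare")
    if kind == "categorical":
        table = pd.crosstab(frame["arm_label"], frame[variable])
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            raise ValidationError("fewer than two non-degenerate categories")
        if np.all(table.to_numpy() == table.to_numpy()[0]):
            # identical rows: chi2_contingency handles, but make p exact
            return GroupComparison("chi_square", 0.0,
                                   ((table.shape[0] - 1) * (table.shape[1] - 1),),
                                   1.0)
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison("chi_square", float(chi2), (int(dof),), float(p))
    if kind == "continuous":
        groups = [g[variable].to_numpy(dtype=float)
                  for _, g in frame.groupby("arm_label")]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            raise ValidationError("fewer than two non-degenerate groups")
        f, p = stats.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(len(g) for g in groups) - len(groups)
        return GroupComparison("anova_F", float(f), (df1, df2), float(p))
    raise ValidationError(f"unknown comparison kind {kind!r}")


def nutrition_summary(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-arm means and proportions of the nutrition and cost outcomes."""
    frame = cohort_to_frame(cohort)
    if frame.empty:
        raise ValidationError("empty cohort")
    rows = {}
    for arm, g in frame.groupby("arm_label"):
        row = {
            "n": len(g),
            "weight_change_mean": g["weight_change_pct"].mean(),
            "weight_change_sd": g["weight_change_pct"].std(ddof=1)
            if len(g) > 1 else 0.0,
        }
        for cat in ("gain", "unchanged", "loss"):
            row[f"weight_{cat}_n"] = int((g["weight_category"] == cat).sum())
        for flag in ("albumin_ge35", "crp_lt15", "lymph_ge1"):
            row[f"{flag}_prop"] = g[flag].mean()
        for col in [c for c in g.columns if c.startswith("cost_")]:
            row[f"{col}_mean"] = g[col].mean()
        row["hospital_days_mean"] = g["hospital_days"].mean()
        rows[arm] = row
    out = pd.DataFrame(rows).T
    out.index.name = "arm_label"
    return out
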