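"""Three-group propensity-score matching on the logit scale.

Arm-membership probabilities come from a multinomial logistic regression
of treatment status on clinical covariates (age, sex, stage, ECOG).
Because the binary "logit of the propensity score" has no unique
three-group analogue, matching uses the logit of the reference-arm
(gastrostomy) membership probability as the matching scalar.  Triplets
are formed 1:1:1 by greedy nearest-neighbor search without replacement,
keeping a triplet only when both within-triplet distances are at most
0.6 times the pooled standard deviation of that logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import PatientRecord, ValidationError, cohort_to_frame

__all__ = [
    "MatchConfig",
    "MatchResult",
    "fit_multinomial_ps",
    "match_triplets",
    "balance_table",
]

COEF_CAP = 15.0


@dataclass(frozen=True)
class MatchConfig:
    covariates: tuple[str, ...] = ("age", "sex", "stage", "ecog")
    caliper_multiplier: float = 0.6
    replacement: bool = False
    reference_arm: str = "PEG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.caliper_multiplier <= 0:
            raise ValidationError("caliper_multiplier must be positive")
        if not self.covariates:
            raise ValidationError("covariates must be non-empty")


@dataclass
class MatchResult:
    """1:1:1 matched triplets plus the fitted score model metadata."""

    triplets: list[tuple[str, str, str]]
    arm_order: tuple[str, str, str]
    ps_model_coefficients: pd.DataFrame | None
    logit_sd: float
    caliper: float
    n_unmatched: int
    logits: pd.Series = field(repr=False, default=None)

    def matched_ids(self) -> set[str]:
        return {sid for trip in self.triplets for sid in trip}

    def to_dict(self) -> dict:
        return {
            "arm_order": list(self.arm_order),
            "triplets": [list(t) for t in self.triplets],
            "coefficients": (self.ps_model_coefficients.to_dict()
                             if self.ps_model_coefficients is not None else None),
            "logit_sd": self.logit_sd,
            "caliper": self.caliper,
            "n_unmatched": self.n_unmatched,
        }


def _design_matrix(frame: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ValidationError(f"covariates not found: {missing}")
    numeric, categorical = [], []
    for c in covariates:
        (numeric if pd.api.types.is_numeric_dtype(frame[c]) else categorical).append(c)
    X = pd.DataFrame(index=frame.index)
    for c in numeric:
        col = frame[c].astype(float)
        scale = col.std(ddof=0)
        # standardize so the separation cap acts on the logit scale
        X[c] = (col - col.mean()) / scale if scale > 0 else col
    if categorical:
        dummies = pd.get_dummies(frame[categorical].astype(str),
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    # constant columns carry no information and break the optimizer
    X = X.loc[:, X.nunique() > 1]
    X.insert(0, "const", 1.0)
    return X


def fit_multinomial_ps(cohort: Sequence[PatientRecord],
                       covariates: Sequence[str]) -> pd.DataFrame:
    """Maximum-likelihood arm-membership probabilities per subject.

    Returns an (n_subjects x n_arms) DataFrame indexed by subject id with
    columns in sorted arm-label order; each row sums to 1.  Perfect or
    near separation is handled by capping coefficient magnitudes at
    +/-15 on the linear scale with a warning.
    """
    frame = cohort_to_frame(cohort)
    arms = sorted(frame["arm_label"].unique())
    if len(arms) < 3:
        raise ValidationError("multinomial propensity scores need >= 3 arms")
    X = _design_matrix(frame, covariates)
    y = pd.Categorical(frame["arm_label"], categories=arms).codes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y, X.to_numpy())
        params = None
        try:
            fit = model.fit(method="newton", maxiter=200, tol=1e-8, disp=0)
            if np.all(np.isfinite(np.asarray(fit.params))):
                params = np.asarray(fit.params)
        except Exception:
            pass
        if params is None:
            # Newton diverges under (quasi-)separation; L-BFGS is robust
            fit = model.fit(method="lbfgs", maxiter=1000, pgtol=1e-8, disp=0)
            params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > COEF_CAP:
        warnings.warn("possible separation in the propensity model; "
                      f"capping coefficients at +/-{COEF_CAP}", stacklevel=2)
        params = np.clip(np.nan_to_num(params, nan=0.0,
                                       posinf=COEF_CAP, neginf=-COEF_CAP),
                         -COEF_CAP, COEF_CAP)
    lin = X.to_numpy() @ params                        # (n, n_arms - 1)
    lin = np.hstack([np.zeros((len(X), 1)), lin])      # reference category 0
    lin -= lin.max(axis=1, keepdims=True)
    probs = np.exp(lin)
    probs /= probs.sum(axis=1, keepdims=True)
    out = pd.DataFrame(probs, columns=arms, index=frame["subject_id"])
    out.attrs["coefficients"] = pd.DataFrame(
        params, index=X.columns, columns=arms[1:])
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1.0 - p))


def match_triplets(cohort: Sequence[PatientRecord], ps: pd.DataFrame,
                   config: MatchConfig) -> MatchResult:
    """Greedy 1:1:1 nearest-neighbor caliper matching without replacement.

    The matching scalar is the logit of the reference-arm membership
    probability; the caliper is ``caliper_multiplier`` times its pooled
    SD.  Reference subjects are processed in ascending order of their
    worst-case nearest-candidate distance (hardest-last), with a seeded
    random shuffle breaking exact ties; a triplet is kept only when the
    nearest unused candidate in *both* other arms lies within the
    caliper.
    """
    frame = cohort_to_frame(cohort)
    arms = sorted(frame["arm_label"].unique())
    if len(arms) != 3:
        raise ValidationError("triplet matching requires exactly 3 arms")
    if config.reference_arm not in arms:
        raise ValidationError(f"reference arm {config.reference_arm!r} absent")
    counts = frame["arm_label"].value_counts()
    if (counts == 0).any():
        raise ValidationError("every arm must contain subjects")

    logits = pd.Series(_logit(ps[config.reference_arm].to_numpy()),
                       index=ps.index)
    logit_sd = float(logits.std(ddof=1))
    caliper = config.caliper_multiplier * logit_sd
    if logit_sd == 0.0:
        caliper = np.inf  # identical scores: every pairing is admissible

    others = [a for a in arms if a != config.reference_arm]
    by_arm = {a: frame.loc[frame["arm_label"] == a, "subject_id"].tolist()
              for a in arms}
    ref_ids = by_arm[config.reference_arm]

    # deterministic greedy order: easiest reference subjects first
    def worst_case(rid: str) -> float:
        d = [min(abs(logits[rid] - logits[c]) for c in by_arm[a]) for a in others]
        return max(d)

    rng = np.random.default_rng(config.seed)
    shuffled = list(rng.permutation(ref_ids))
    order = sorted(shuffled, key=worst_case)

    available = {a: set(by_arm[a]) for a in others}
    triplets: list[tuple[str, str, str]] = []
    n_unmatched = 0
    for rid in order:
        chosen = []
        for a in others:
            pool = available[a]
            if not pool:
                chosen = None
                break
            cid = min(pool, key=lambda c: (abs(logits[rid] - logits[c]), c))
            if abs(logits[rid] - logits[cid]) > caliper:
                chosen = None
                break
            chosen.append(cid)
        if chosen is None:
            n_unmatched += 1
            continue
        if not config.replacement:
            for a, cid in zip(others, chosen):
                available[a].discard(cid)
        triplets.append((rid, *chosen))

    result = MatchResult(
        triplets=triplets,
        arm_order=(config.reference_arm, *others),
        ps_model_coefficients=ps.attrs.get("coefficients"),
        logit_sd=logit_sd,
        caliper=float(caliper),
        n_unmatched=n_unmatched,
        logits=logits,
    )
    _assert_valid(result, config)
    return result


def _assert_valid(result: MatchResult, config: MatchConfig) -> None:
    if not config.replacement:
        ids = [sid for t in result.triplets for sid in t]
        if len(ids) != len(set(ids)):
            raise AssertionError("subject reused despite matching without "
                                 "replacement")
    for rid, *others in result.triplets:
        for cid in others:
            if abs(result.logits[rid] - result.logits[cid]) > result.caliper + 1e-12:
                raise AssertionError("within-triplet distance exceeds caliper")


def balance_table(cohort: Sequence[PatientRecord], result: MatchResult,
                  covariates: Sequence[str] = ("age", "sex", "stage", "ecog"),
                  ) -> pd.DataFrame:
    """Balance diagnostics per covariate and arm pair.

    Continuous covariates use the standardized mean difference
    (m1 - m2) / sqrt((v1 + v2) / 2); each level of a categorical
    covariate is compared as a raw proportion difference (already on a
    bounded scale, and robust when a level is absent from one arm).
    Rows cover both the full cohort ("before") and the matched triplets
    ("after").
    """
    frame = cohort_to_frame(cohort).set_index("subject_id")
    arms = sorted(frame["arm_label"].unique())
    matched = frame.loc[sorted(result.matched_ids())] if result.triplets else \
        frame.iloc[0:0]

    def smd(a: np.ndarray, b: np.ndarray) -> float:
        m1, m2 = a.mean(), b.mean()
        v1 = a.var(ddof=1) if len(a) > 1 else 0.0
        v2 = b.var(ddof=1) if len(b) > 1 else 0.0
        denom = np.sqrt((v1 + v2) / 2.0)
        if denom == 0:
            return 0.0
        return float((m1 - m2) / denom)

    rows = []
    for stage_name, data in (("before", frame), ("after", matched)):
        if data.empty:
            continue
        for cov in covariates:
            if pd.api.types.is_numeric_dtype(data[cov]):
                columns = {cov: (data[cov].astype(float), True)}
            else:
                columns = {f"{cov}={lvl}": ((data[cov].astype(str) == lvl)
                                            .astype(float), False)
                           for lvl in sorted(frame[cov].astype(str).unique())}
            for name, (series, standardize) in columns.items():
                for i, a1 in enumerate(arms):
                    for a2 in arms[i + 1:]:
                        g1 = series[data["arm_label"] == a1].to_numpy()
                        g2 = series[data["arm_label"] == a2].to_numpy()
                        if len(g1) == 0 or len(g2) == 0:
                            continue
                        value = smd(g1, g2) if standardize else \
                            float(g1.mean() - g2.mean())
                        rows.append({"stage": stage_name, "covariate": name,
                                     "arm_1": a1, "arm_2": a2,
                                     "smd": value})
    return pd.DataFrame(rows)
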