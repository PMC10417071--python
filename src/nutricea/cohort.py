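"""Seeded synthetic three-arm trial cohorts.

Generates patient-level records for the three enteral nutrition support
strategies (PEG gastrostomy, nasogastric tube feeding, oral supplements)
whose summary statistics reproduce the published group-level tables:
weight-change moments and categories, nutrition-marker proportions,
tumour-response distribution, 1-year loco-regional progression-free and
overall survival, and itemized treatment costs.

Event times follow constant hazards calibrated in closed form to the
1-year survival proportions: progression and death are competing
exponentials whose combined 1-year survival equals the LRFS rate and
whose death margin equals the OS rate.  The continuous weight change is
a three-component truncated-normal mixture whose component weights are
the published gain/unchanged/loss proportions; the latent normal is
calibrated numerically so that the mixture mean and SD equal the
published mean and SD (using the published moments directly as the
latent parameters would bias the mixture mean, because the category
weights are not the normal's own region masses).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ArmProfile",
    "PatientRecord",
    "generate_cohort",
    "generate_trial",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: band (in percent weight change) separating "unchanged" from gain/loss
WEIGHT_UNCHANGED_BAND = 1.0

#: coefficient of variation for gamma-distributed cost items and hospital days
COST_CV = 0.3

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")
WEIGHT_LEVELS = ("gain", "unchanged", "loss")


class ValidationError(ValueError):
    """Raised when a profile or record violates its invariants."""


def _check_probs(name: str, p: Sequence[float], k: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (k,):
        raise ValidationError(f"{name} must have length {k}, got shape {p.shape}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} must be non-negative and sum to 1, got {p}")
    return p


@dataclass(frozen=True)
class ArmProfile:
    """Published group-level summary of one trial arm.

    Probabilities are proportions from the outcome tables; costs are
    mean USD per item; survival entries are 1-year rates in (0, 1].
    """

    arm_label: str
    n: int
    weight_change_mean: float
    weight_change_sd: float
    weight_category_probs: Sequence[float]  # gain / unchanged / loss
    albumin_ge35_prob: float
    crp_lt15_prob: float
    lymph_ge1_prob: float
    response_probs: Sequence[float]  # CR / PR / SD / PD
    lrfs_1yr: float
    os_1yr: float
    cost_means: Mapping[str, float]
    hospital_days_mean: float
    age_range: tuple[float, float]
    sex_male_prob: float
    stage_probs: Mapping[str, float]
    ecog_probs: Mapping[str, float]
    baseline_weight_mean: float = 58.4
    baseline_weight_sd: float = 9.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if self.weight_change_sd < 0:
            raise ValidationError("weight_change_sd must be >= 0")
        _check_probs("weight_category_probs", self.weight_category_probs, 3)
        _check_probs("response_probs", self.response_probs, 4)
        for name in ("albumin_ge35_prob", "crp_lt15_prob", "lymph_ge1_prob",
                     "sex_male_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("lrfs_1yr", "os_1yr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.lrfs_1yr > self.os_1yr:
            raise ValidationError("lrfs_1yr cannot exceed os_1yr")
        for probs, k in ((self.stage_probs, len(self.stage_probs)),
                         (self.ecog_probs, len(self.ecog_probs))):
            _check_probs("category probs", list(probs.values()), k)
        if any(m < 0 for m in self.cost_means.values()):
            raise ValidationError("cost means must be non-negative")
        if self.age_range[0] > self.age_range[1]:
            raise ValidationError("age_range must be (low, high)")

    def latent_weight_params(self) -> tuple[float, float]:
        """Latent normal (mu, sigma) reproducing the published weight moments.

        Solves two equations (mixture mean, mixture SD) in two unknowns,
        where the mixture weights are ``weight_category_probs`` and the
        components are the latent normal truncated to (band, inf),
        (-band, band) and (-inf, -band).
        """
        cached = getattr(self, "_latent_cache", None)
        if cached is not None:
            return cached
        if self.weight_change_sd == 0:
            object.__setattr__(self, "_latent_cache",
                               (self.weight_change_mean, 0.0))
            return self.weight_change_mean, 0.0
        w = np.asarray(self.weight_category_probs, float)
        b = WEIGHT_UNCHANGED_BAND
        target = np.array([self.weight_change_mean, self.weight_change_sd])

        def moments(x: np.ndarray) -> np.ndarray:
            mu, sigma = x
            sigma = abs(sigma)
            bounds = [((b - mu) / sigma, np.inf),
                      ((-b - mu) / sigma, (b - mu) / sigma),
                      (-np.inf, (-b - mu) / sigma)]
            m1 = m2 = 0.0
            for wi, (lo, hi) in zip(w, bounds):
                if wi == 0:
                    continue
                d = stats.truncnorm(lo, hi, loc=mu, scale=sigma)
                mean = d.mean()
                m1 += wi * mean
                m2 += wi * (d.var() + mean ** 2)
            return np.array([m1, np.sqrt(max(m2 - m1 ** 2, 0.0))])

        sol = optimize.fsolve(lambda x: moments(x) - target,
                              x0=target.copy(), full_output=True)
        x, info, ier, _ = sol
        if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-6:
            raise ValidationError(
                "could not calibrate latent weight-change distribution for "
                f"arm {self.arm_label!r}")
        latent = (float(x[0]), float(abs(x[1])))
        object.__setattr__(self, "_latent_cache", latent)
        return latent


@dataclass
class PatientRecord:
    """One synthetic subject with covariates, outcomes and costs."""

    subject_id: str
    arm_label: str
    age: float
    sex: str
    stage: str
    ecog: str
    baseline_weight: float
    weight_change_pct: float
    weight_category: str
    albumin_ge35: bool
    crp_lt15: bool
    lymph_ge1: bool
    response: str
    lrfs_time: float
    lrfs_event: bool
    os_time: float
    os_event: bool
    costs: dict[str, float] = field(default_factory=dict)
    hospital_days: float = 0.0


def _truncnorm_sample(rng: np.random.Generator, mu: float, sigma: float,
                      lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Inverse-CDF truncated-normal draws with per-element bounds."""
    a = special.ndtr((lo - mu) / sigma)
    b = special.ndtr((hi - mu) / sigma)
    u = rng.uniform(a, b)
    return mu + sigma * special.ndtri(u)


def _exponential_times(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def generate_cohort(profile: ArmProfile, seed: int,
                    censor_horizon: float = 3.0) -> list[PatientRecord]:
    """Draw ``profile.n`` subjects for one arm.

    The same (profile, seed, horizon) triple always yields bit-identical
    records.  Event times are competing exponentials: the death hazard is
    ``-ln(os_1yr)`` per year and the progression hazard ``ln(os/lrfs)``,
    so that the combined 1-year event-free fraction equals ``lrfs_1yr``.
    A rate of zero (1-year survival of 1) yields administrative censoring
    at the horizon for every subject.
    """
    if censor_horizon <= 0:
        raise ValidationError("censor_horizon must be positive")
    rng = np.random.default_rng(int(seed))
    n = profile.n

    age = rng.uniform(profile.age_range[0], profile.age_range[1], n).round(1)
    sex = np.where(rng.random(n) < profile.sex_male_prob, "male", "female")
    stage_levels = list(profile.stage_probs)
    stage = rng.choice(stage_levels, size=n, p=list(profile.stage_probs.values()))
    ecog_levels = list(profile.ecog_probs)
    ecog = rng.choice(ecog_levels, size=n, p=list(profile.ecog_probs.values()))
    baseline_weight = rng.normal(profile.baseline_weight_mean,
                                 profile.baseline_weight_sd, n).round(1)

    cat_idx = rng.choice(3, size=n, p=np.asarray(profile.weight_category_probs))
    mu, sigma = profile.latent_weight_params()
    b = WEIGHT_UNCHANGED_BAND
    lo = np.array([b, -b, -np.inf])[cat_idx]
    hi = np.array([np.inf, b, -b])[cat_idx]
    if sigma == 0:
        weight_change = np.full(n, mu)
    else:
        weight_change = _truncnorm_sample(rng, mu, sigma, lo, hi)

    albumin = rng.random(n) < profile.albumin_ge35_prob
    crp = rng.random(n) < profile.crp_lt15_prob
    lymph = rng.random(n) < profile.lymph_ge1_prob
    response = rng.choice(RESPONSE_LEVELS, size=n,
                          p=np.asarray(profile.response_probs))

    death_rate = -np.log(profile.os_1yr)
    prog_rate = np.log(profile.os_1yr / profile.lrfs_1yr)
    t_death = _exponential_times(rng, death_rate, n)
    t_prog = _exponential_times(rng, prog_rate, n)
    t_lrfs = np.minimum(t_prog, t_death)
    lrfs_time = np.minimum(t_lrfs, censor_horizon)
    lrfs_event = t_lrfs <= censor_horizon
    os_time = np.minimum(t_death, censor_horizon)
    os_event = t_death <= censor_horizon

    items = list(profile.cost_means)
    shape = 1.0 / COST_CV ** 2
    cost_draws = {
        item: rng.gamma(shape, profile.cost_means[item] / shape, n)
        if profile.cost_means[item] > 0 else np.zeros(n)
        for item in items
    }
    hospital_days = rng.gamma(shape, profile.hospital_days_mean / shape, n)

    records = []
    for i in range(n):
        records.append(PatientRecord(
            subject_id=f"{profile.arm_label}-{i + 1:04d}",
            arm_label=profile.arm_label,
            age=float(age[i]),
            sex=str(sex[i]),
            stage=str(stage[i]),
            ecog=str(ecog[i]),
            baseline_weight=float(baseline_weight[i]),
            weight_change_pct=float(weight_change[i]),
            weight_category=WEIGHT_LEVELS[cat_idx[i]],
            albumin_ge35=bool(albumin[i]),
            crp_lt15=bool(crp[i]),
            lymph_ge1=bool(lymph[i]),
            response=str(response[i]),
            lrfs_time=float(lrfs_time[i]),
            lrfs_event=bool(lrfs_event[i]),
            os_time=float(os_time[i]),
            os_event=bool(os_event[i]),
            costs={item: float(cost_draws[item][i]) for item in items},
            hospital_days=float(hospital_days[i]),
        ))
    return records


def _arm_subseed(master_seed: int, arm_label: str) -> int:
    # stable across processes (unlike hash()) and independent of arm order
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(arm_label.encode())) % (2 ** 31)


def generate_trial(profiles: Sequence[ArmProfile], seed: int,
                   censor_horizon: float = 3.0) -> list[PatientRecord]:
    """Concatenate per-arm cohorts with label-derived sub-seeds.

    Sub-seeds depend only on the master seed and the arm label, so
    permuting the profile order changes only the concatenation order,
    never the per-arm records.
    """
    if len(profiles) < 2:
        raise ValidationError("generate_trial needs at least two arm profiles")
    labels = [p.arm_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate arm labels: {labels}")
    records: list[PatientRecord] = []
    for profile in profiles:
        records.extend(generate_cohort(
            profile, _arm_subseed(seed, profile.arm_label), censor_horizon))
    return records


# ---------------------------------------------------------------------------
# CSV round-trip (cost items flattened into cost_<item> columns)

_SCALAR_FIELDS = [f.name for f in fields(PatientRecord)
                  if f.name not in ("costs",)]


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    if not cohort:
        raise ValidationError("empty cohort")
    rows = []
    for rec in cohort:
        row = {name: getattr(rec, name) for name in _SCALAR_FIELDS}
        row.update({f"cost_{item}": v for item, v in rec.costs.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    cost_cols = [c for c in frame.columns if c.startswith("cost_")]
    records = []
    for _, row in frame.iterrows():
        kwargs = {name: row[name] for name in _SCALAR_FIELDS}
        for name in ("albumin_ge35", "crp_lt15", "lymph_ge1",
                     "lrfs_event", "os_event"):
            kwargs[name] = bool(kwargs[name])
        kwargs["costs"] = {c[len("cost_"):]: float(row[c]) for c in cost_cols}
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path, float_precision="round_trip"))
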