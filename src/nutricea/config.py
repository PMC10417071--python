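"""Configuration loading: arm profiles, model specs and analysis settings.

The shipped default configuration (``data/default_config.yaml``) carries
the published per-arm summary tables, the trial design parameters, and
the decision-model defaults, so the whole pipeline runs without any
external input.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .cea import CEAConfig
from .cohort import ArmProfile
from .markov import STATES, MarkovSpec, calibrate_annual_probs
from .matching import MatchConfig
from .trial import PowerSpec

__all__ = [
    "load_config",
    "default_config",
    "profiles_from_config",
    "power_spec_from_config",
    "match_config_from_config",
    "cea_config_from_config",
    "strategy_specs_from_config",
]


def default_config() -> dict:
    text = (importlib.resources.files("nutricea") / "data"
            / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Read a YAML or JSON configuration; ``None`` loads the shipped default."""
    if path is None:
        return default_config()
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _profile_from_entry(entry: Mapping[str, Any]) -> ArmProfile:
    n = int(entry["n"])

    def props(counts) -> list[float]:
        counts = np.asarray(counts, dtype=float)
        return list(counts / counts.sum())

    stage = {k: v / n for k, v in entry["stage_counts"].items()}
    ecog = {str(k): v / n for k, v in entry["ecog_counts"].items()}
    return ArmProfile(
        arm_label=entry["arm_label"],
        n=n,
        weight_change_mean=float(entry["weight_change_mean"]),
        weight_change_sd=float(entry["weight_change_sd"]),
        weight_category_probs=props(entry["weight_category_counts"]),
        albumin_ge35_prob=entry["albumin_ge35_count"] / n,
        crp_lt15_prob=entry["crp_lt15_count"] / n,
        lymph_ge1_prob=entry["lymph_ge1_count"] / n,
        response_probs=props(entry["response_counts"]),
        lrfs_1yr=float(entry["lrfs_1yr"]),
        os_1yr=float(entry["os_1yr"]),
        cost_means=dict(entry["cost_means"]),
        hospital_days_mean=float(entry["hospital_days_mean"]),
        age_range=tuple(entry["age_range"]),
        sex_male_prob=entry["sex_male_count"] / n,
        stage_probs=stage,
        ecog_probs=ecog,
    )


def profiles_from_config(config: Mapping[str, Any]) -> list[ArmProfile]:
    return [_profile_from_entry(e) for e in config["arms"]]


def power_spec_from_config(config: Mapping[str, Any]) -> PowerSpec:
    return PowerSpec(**config["power"])


def match_config_from_config(config: Mapping[str, Any], seed: int = 0) -> MatchConfig:
    entry = dict(config["match"])
    entry["covariates"] = tuple(entry["covariates"])
    return MatchConfig(seed=seed, **entry)


def cea_config_from_config(config: Mapping[str, Any],
                           seed: int | None = None) -> CEAConfig:
    entry = dict(config["cea"])
    entry["wtp_grid"] = tuple(float(x) for x in entry["wtp_grid"])
    entry["headline_thresholds"] = tuple(
        float(x) for x in entry["headline_thresholds"])
    if seed is not None:
        entry["seed"] = seed
    return CEAConfig(**entry)


def strategy_specs_from_config(config: Mapping[str, Any]) -> dict[str, MarkovSpec]:
    """One calibrated Markov spec per arm.

    Transitions come from the arm's 1-year survival rates via
    :func:`calibrate_annual_probs`; the one-time treatment cost is the
    arm's observed 6-month total cost.
    """
    m = config["markov"]
    utilities = np.array([m["utilities"][s] for s in STATES])
    state_costs = np.array([m["state_costs"][s] for s in STATES])
    specs = {}
    for entry in config["arms"]:
        transitions = calibrate_annual_probs(
            entry["lrfs_1yr"], entry["os_1yr"],
            m["relapse_mortality"], m["background_mortality"])
        specs[entry["arm_label"]] = MarkovSpec(
            transitions=transitions,
            utilities=utilities.copy(),
            state_costs=state_costs.copy(),
            one_time_cost=float(entry["total_6mo_cost"]),
            discount_rate=float(m["discount_rate"]),
            cycle_length=float(m["cycle_length"]),
            horizon_cycles=int(m["horizon_cycles"]),
            label=entry["arm_label"],
        )
    return specs
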