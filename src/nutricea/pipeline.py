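"""End-to-end orchestration: generate -> analyze -> match -> markov -> cea.

Each stage reads the shared configuration dictionary, writes its
artifacts into the output directory, and contributes a section to a
consolidated JSON report that embeds the configuration and seed needed
to regenerate it exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .cea import (acceptability_report, default_psa_distributions,
                  icer_frontier, net_monetary_benefit, run_psa)
from .cohort import (ValidationError, generate_trial, read_cohort_csv,
                     write_cohort_csv)
from .config import (cea_config_from_config, load_config,
                     match_config_from_config, power_spec_from_config,
                     profiles_from_config, strategy_specs_from_config)
from .markov import life_expectancy, run_cohort
from .matching import balance_table, fit_multinomial_ps, match_triplets
from .trial import (compare_groups, km_estimate, nutrition_summary,
                    planned_enrollment, required_sample_size, survival_at)

logger = logging.getLogger("nutricea")

ALL_STAGES = ("generate", "analyze", "match", "markov", "cea")


class DependencyError(RuntimeError):
    """An enabled stage is missing its upstream artifact."""


@dataclass
class PipelineConfig:
    """Run settings: stage toggles, seed, paths, analysis configuration."""

    config: Mapping[str, Any] = field(default_factory=load_config)
    seed: int = 0
    out_dir: Path = Path("results")
    stages: tuple[str, ...] = ALL_STAGES
    cohort_csv: Path | None = None      # optional pre-existing cohort input

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        self.out_dir = Path(self.out_dir)


def run_pipeline(pipeline: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle."""
    out = pipeline.out_dir
    out.mkdir(parents=True, exist_ok=True)
    config = pipeline.config
    report: dict[str, Any] = {
        "version": __version__,
        "seed": pipeline.seed,
        "stages": list(pipeline.stages),
        "config": _jsonable(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    cohort = None
    if "generate" in pipeline.stages:
        logger.info("generating synthetic trial cohort (seed=%d)", pipeline.seed)
        profiles = profiles_from_config(config)
        cohort = generate_trial(profiles, seed=pipeline.seed)
        write_cohort_csv(cohort, out / "cohort.csv")
        report["generate"] = {"n_subjects": len(cohort),
                              "arms": [p.arm_label for p in profiles],
                              "cohort_csv": str(out / "cohort.csv")}
    elif pipeline.cohort_csv is not None:
        cohort = read_cohort_csv(pipeline.cohort_csv)

    def need_cohort(stage: str):
        if cohort is None:
            raise DependencyError(
                f"stage {stage!r} needs a cohort: enable 'generate' or "
                "provide cohort_csv")
        return cohort

    if "analyze" in pipeline.stages:
        records = need_cohort("analyze")
        logger.info("computing trial statistics")
        spec = power_spec_from_config(config)
        n_required = required_sample_size(spec)
        summary = nutrition_summary(records)
        summary.to_csv(out / "nutrition_summary.csv")
        survival = {}
        for endpoint, time_col, event_col in (
                ("lrfs", "lrfs_time", "lrfs_event"),
                ("os", "os_time", "os_event")):
            survival[endpoint] = {}
            for arm in sorted({r.arm_label for r in records}):
                sub = [r for r in records if r.arm_label == arm]
                est = km_estimate([getattr(r, time_col) for r in sub],
                                  [getattr(r, event_col) for r in sub])
                survival[endpoint][arm] = {
                    "at_1yr": survival_at(est, 1.0)}
        weight_cmp = compare_groups(records, "weight_category", "categorical")
        report["analyze"] = {
            "required_sample_size": n_required,
            "planned_enrollment": planned_enrollment(n_required,
                                                     spec.dropout_rate),
            "survival_1yr": survival,
            "weight_category_test": {
                "statistic": weight_cmp.statistic_value,
                "p_value": weight_cmp.p_value},
            "nutrition_summary_csv": str(out / "nutrition_summary.csv"),
        }

    if "match" in pipeline.stages:
        records = need_cohort("match")
        logger.info("propensity-score matching")
        mconfig = match_config_from_config(config, seed=pipeline.seed)
        ps = fit_multinomial_ps(records, mconfig.covariates)
        result = match_triplets(records, ps, mconfig)
        balance = balance_table(records, result, mconfig.covariates)
        balance.to_csv(out / "balance.csv", index=False)
        (out / "match_result.json").write_text(
            json.dumps(result.to_dict(), indent=2))
        report["match"] = {
            "n_triplets": len(result.triplets),
            "n_unmatched": result.n_unmatched,
            "caliper": result.caliper,
            "logit_sd": result.logit_sd,
            "max_abs_smd_after": float(
                balance.loc[balance["stage"] == "after", "smd"].abs().max())
            if (balance["stage"] == "after").any() else None,
        }

    strategy_results = None
    if "markov" in pipeline.stages:
        logger.info("running Markov cohort models")
        specs = strategy_specs_from_config(config)
        strategy_results = {}
        markov_report = {}
        for label, spec in specs.items():
            trace, result = run_cohort(spec)
            trace.to_frame().to_csv(out / f"trace_{label}.csv", index=False)
            strategy_results[label] = result
            markov_report[label] = {
                "total_cost": result.total_cost,
                "total_qalys": result.total_qalys,
                "life_expectancy": life_expectancy(spec),
            }
        report["markov"] = markov_report

    if "cea" in pipeline.stages:
        if strategy_results is None:
            raise DependencyError("stage 'cea' needs stage 'markov'")
        logger.info("cost-effectiveness analysis")
        cea_cfg = cea_config_from_config(config, seed=pipeline.seed)
        frontier = icer_frontier(list(strategy_results.values()))
        frontier.summary().to_csv(out / "frontier.csv")
        specs = strategy_specs_from_config(config)
        dists = default_psa_distributions(specs, cea_cfg)
        psa = run_psa(specs, dists, cea_cfg)
        psa.ceac.to_csv(out / "ceac.csv")
        report_table = acceptability_report(psa, cea_cfg)
        report_table.to_csv(out / "acceptability.csv")
        nmb = {lbl: {str(int(w)): net_monetary_benefit(res, w)
                     for w in cea_cfg.wtp_grid}
               for lbl, res in strategy_results.items()}
        report["cea"] = {
            "frontier": frontier.summary().reset_index().to_dict("records"),
            "sequential_icers": frontier.sequential_icers,
            "nmb": nmb,
            "acceptability": report_table.reset_index().to_dict("records"),
            "psa_draws": cea_cfg.psa_draws,
            "n_renormalized": psa.n_renormalized,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.info("report written to %s", out / "report.json")
    return report


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
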