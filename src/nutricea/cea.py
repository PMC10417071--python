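"""Cost-effectiveness comparison of nutrition-support strategies.

Implements the incremental cost-effectiveness ratio (ICER) efficiency
frontier with strong and extended dominance, net monetary benefit
(NMB = WTP x QALY - cost), one-way (tornado) sensitivity of the ICER,
and probabilistic sensitivity analysis (PSA) with cost-effectiveness
acceptability curves (CEACs).  PSA samples beta distributions for
probabilities and utilities and gamma distributions for costs, using
common random numbers across strategies within each draw so that
between-strategy differences are not inflated by sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markov import MarkovSpec, StrategyResult, get_param, run_cohort, set_param

__all__ = [
    "CEAConfig",
    "FrontierResult",
    "ParamDistribution",
    "PSAResult",
    "icer_frontier",
    "net_monetary_benefit",
    "one_way_sensitivity",
    "run_psa",
    "acceptability_report",
    "default_psa_distributions",
]


class CEAValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CEAConfig:
    wtp_grid: tuple[float, ...] = tuple(range(0, 50_001, 5_000))
    headline_thresholds: tuple[float, float] = (10_000.0, 50_000.0)
    cost_effective_threshold: float = 33_962.0
    psa_draws: int = 10_000
    seed: int = 0
    cny_per_usd: float = 6.37
    rel_sd_probability: float = 0.10
    rel_sd_utility: float = 0.10
    rel_sd_cost: float = 0.30

    def __post_init__(self) -> None:
        grid = np.asarray(self.wtp_grid, dtype=float)
        if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
            raise CEAValidationError("wtp_grid must be sorted and non-negative")
        if self.psa_draws <= 0:
            raise CEAValidationError("psa_draws must be positive")


# ---------------------------------------------------------------------------
# Frontier


@dataclass
class FrontierResult:
    """Strategies ordered by ascending cost with dominance flags."""

    ordered_strategies: list[StrategyResult]
    on_frontier: dict[str, bool]
    strongly_dominated: dict[str, bool]
    extendedly_dominated: dict[str, bool]
    sequential_icers: dict[str, float]   # frontier members except the cheapest
    tie_flagged: bool = False

    @property
    def frontier_labels(self) -> list[str]:
        return [s.strategy_label for s in self.ordered_strategies
                if self.on_frontier[s.strategy_label]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.ordered_strategies:
            lbl = s.strategy_label
            rows.append({
                "strategy": lbl,
                "cost_usd": s.total_cost,
                "qalys": s.total_qalys,
                "on_frontier": self.on_frontier[lbl],
                "strongly_dominated": self.strongly_dominated[lbl],
                "extendedly_dominated": self.extendedly_dominated[lbl],
                "icer_vs_previous": self.sequential_icers.get(lbl, np.nan),
            })
        return pd.DataFrame(rows).set_index("strategy")


def icer_frontier(results: Sequence[StrategyResult]) -> FrontierResult:
    """Efficiency frontier with strong and iterative extended dominance.

    Strategies are sorted by ascending cost; a strategy costing at least
    as much as another while yielding no more QALYs (one inequality
    strict) is strongly dominated; remaining strategies whose sequential
    ICER is not strictly below the next member's are removed iteratively
    (extended dominance) until the sequential ICERs strictly increase.
    """
    if len(results) < 2:
        raise CEAValidationError("frontier needs at least two strategies")
    labels = [r.strategy_label for r in results]
    if len(set(labels)) != len(labels):
        raise CEAValidationError(f"duplicate strategy labels: {labels}")

    tie_flagged = len({(r.total_cost, r.total_qalys) for r in results}) < len(results)
    ordered = sorted(results, key=lambda r: (r.total_cost, r.strategy_label))

    strongly = {r.strategy_label: False for r in results}
    for r in ordered:
        for other in ordered:
            if other is r:
                continue
            tie = (other.total_cost == r.total_cost
                   and other.total_qalys == r.total_qalys)
            if (other.total_cost <= r.total_cost
                    and other.total_qalys >= r.total_qalys
                    and (other.total_cost < r.total_cost
                         or other.total_qalys > r.total_qalys)) \
                    or (tie and other.strategy_label < r.strategy_label):
                strongly[r.strategy_label] = True
                break

    extendedly = {r.strategy_label: False for r in results}
    frontier = [r for r in ordered if not strongly[r.strategy_label]]

    def seq_icers(members: list[StrategyResult]) -> list[float]:
        return [(b.total_cost - a.total_cost) / (b.total_qalys - a.total_qalys)
                for a, b in zip(members, members[1:])]

    while len(frontier) > 2:
        icers = seq_icers(frontier)
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                victim = frontier[i + 1]
                extendedly[victim.strategy_label] = True
                frontier.pop(i + 1)
                removed = True
                break
        if not removed:
            break

    on_frontier = {lbl: False for lbl in labels}
    sequential = {}
    for i, member in enumerate(frontier):
        on_frontier[member.strategy_label] = True
        if i > 0:
            prev = frontier[i - 1]
            sequential[member.strategy_label] = (
                (member.total_cost - prev.total_cost)
                / (member.total_qalys - prev.total_qalys))
    return FrontierResult(ordered, on_frontier, strongly, extendedly,
                          sequential, tie_flagged)


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost, in USD."""
    if wtp < 0:
        raise CEAValidationError("willingness-to-pay must be non-negative")
    return wtp * result.total_qalys - result.total_cost


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity


def _apply(spec: MarkovSpec, path: str, value: float) -> MarkovSpec:
    new, _ = set_param(spec, path, value)
    return new


def _pair_icer(spec_low_cost: MarkovSpec, spec_high_cost: MarkovSpec) -> float:
    _, a = run_cohort(spec_low_cost)
    _, b = run_cohort(spec_high_cost)
    return (b.total_cost - a.total_cost) / (b.total_qalys - a.total_qalys)


def one_way_sensitivity(base_specs: Mapping[str, MarkovSpec],
                        parameter_ranges: Mapping[str, tuple[float, float]],
                        comparison: tuple[str, str]) -> pd.DataFrame:
    """Tornado table of the pairwise ICER over one-at-a-time parameter sweeps.

    ``comparison`` is (comparator, intervention); each parameter path may
    be prefixed ``"<strategy>:"`` to vary it in a single strategy,
    otherwise it is varied in both simultaneously.  Rows are sorted by
    descending ICER swing.
    """
    comp_label, int_label = comparison
    for lbl in comparison:
        if lbl not in base_specs:
            raise CEAValidationError(f"strategy {lbl!r} not in base_specs")
    base_pair = {lbl: base_specs[lbl] for lbl in comparison}
    base_icer = _pair_icer(base_pair[comp_label], base_pair[int_label])

    rows = []
    for raw_path, (low, high) in parameter_ranges.items():
        if ":" in raw_path:
            target, path = raw_path.split(":", 1)
            if target not in base_pair:
                raise CEAValidationError(f"unknown strategy in path {raw_path!r}")
            targets = [target]
        else:
            path, targets = raw_path, list(base_pair)
        base_value = get_param(base_pair[targets[0]], path)
        if not (min(low, high) <= base_value <= max(low, high)):
            raise CEAValidationError(
                f"range for {raw_path!r} must contain the base value "
                f"{base_value}")
        icers = {}
        for bound_name, bound in (("low", low), ("high", high)):
            specs = dict(base_pair)
            for t in targets:
                specs[t] = _apply(specs[t], path, bound)
            icers[bound_name] = _pair_icer(specs[comp_label], specs[int_label])
        rows.append({
            "parameter": raw_path,
            "low_bound": low, "high_bound": high,
            "icer_at_low": icers["low"], "icer_at_high": icers["high"],
            "swing": abs(icers["high"] - icers["low"]),
        })
    out = pd.DataFrame(rows).sort_values(
        ["swing", "parameter"], ascending=[False, True]).reset_index(drop=True)
    out.attrs["base_icer"] = base_icer
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class ParamDistribution:
    """Sampling distribution for one model parameter.

    ``family`` is ``beta`` (probabilities and utilities), ``gamma``
    (non-negative costs) or ``fixed``; shapes are derived from the mean
    and a relative SD by method of moments.  ``strategy=None`` applies
    the same sampled value to every strategy (a shared parameter);
    otherwise only the named strategy is perturbed.
    """

    path: str
    family: str
    mean: float
    rel_sd: float
    strategy: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise CEAValidationError(f"unknown family {self.family!r}")
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise CEAValidationError("beta requires a mean in [0, 1]")
        if self.family == "gamma" and self.mean < 0:
            raise CEAValidationError("gamma requires a non-negative mean")
        if self.rel_sd < 0:
            raise CEAValidationError("rel_sd must be non-negative")

    def ppf(self, u: float) -> float:
        if self.family == "fixed" or self.rel_sd == 0 or self.mean == 0:
            return self.mean
        sd = self.rel_sd * abs(self.mean)
        if self.family == "beta":
            m = self.mean
            v = min(sd ** 2, m * (1 - m) * 0.999)  # keep shapes positive
            if v <= 0:
                return m
            nu = m * (1 - m) / v - 1.0
            return float(stats.beta.ppf(u, m * nu, (1 - m) * nu))
        shape = 1.0 / self.rel_sd ** 2
        return float(stats.gamma.ppf(u, shape, scale=self.mean / shape))


@dataclass
class PSAResult:
    """Per-draw (cost, QALY) pairs per strategy and the derived CEACs."""

    draws: dict[str, np.ndarray]          # label -> (n_draws, 2) [cost, qaly]
    ceac: pd.DataFrame                    # index wtp, columns strategies
    wtp_grid: np.ndarray
    n_renormalized: int = 0
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for lbl, arr in self.draws.items():
            rows.append({"strategy": lbl,
                         "mean_cost": arr[:, 0].mean(),
                         "mean_qalys": arr[:, 1].mean()})
        return pd.DataFrame(rows).set_index("strategy")


def default_psa_distributions(base_specs: Mapping[str, MarkovSpec],
                              config: CEAConfig) -> list[ParamDistribution]:
    """Standard distribution set for the shipped model.

    Utilities are shared beta parameters; per-strategy transition
    probabilities are betas; per-strategy one-time and state costs are
    gammas.  Zero-valued parameters stay fixed.
    """
    dists: list[ParamDistribution] = []
    any_spec = next(iter(base_specs.values()))
    for state, idx in (("disease_free", 0), ("relapse", 1)):
        dists.append(ParamDistribution(
            f"utilities.{state}", "beta", float(any_spec.utilities[idx]),
            config.rel_sd_utility))
    for lbl, spec in base_specs.items():
        for path in ("transitions.disease_free.relapse",
                     "transitions.disease_free.death",
                     "transitions.relapse.death"):
            mean = get_param(spec, path)
            if mean > 0:
                dists.append(ParamDistribution(
                    path, "beta", mean, config.rel_sd_probability, strategy=lbl))
        for path in ("one_time_cost", "state_costs.disease_free",
                     "state_costs.relapse"):
            mean = get_param(spec, path)
            if mean > 0:
                dists.append(ParamDistribution(
                    path, "gamma", mean, config.rel_sd_cost, strategy=lbl))
    return dists


def run_psa(base_specs: Mapping[str, MarkovSpec],
            distributions: Sequence[ParamDistribution],
            config: CEAConfig) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Each draw samples one uniform per distribution (common random
    numbers: a shared distribution perturbs every strategy identically),
    rebuilds the specs, runs each strategy's cohort model and records
    (cost, QALY).  Transition rows pushed outside [0, 1] by sampling are
    renormalized; the count of such repairs is reported.
    """
    labels = list(base_specs)
    rng = np.random.default_rng(config.seed)
    n = config.psa_draws
    u = rng.random((n, len(distributions)))
    draws = {lbl: np.empty((n, 2)) for lbl in labels}
    n_renorm = 0
    for d in range(n):
        specs = {lbl: base_specs[lbl] for lbl in labels}
        for k, dist in enumerate(distributions):
            value = dist.ppf(u[d, k])
            targets = labels if dist.strategy is None else [dist.strategy]
            for lbl in targets:
                specs[lbl], renorm = set_param(specs[lbl], dist.path, value)
                n_renorm += int(renorm)
        for lbl in labels:
            _, res = run_cohort(specs[lbl])
            draws[lbl][d] = (res.total_cost, res.total_qalys)
    if n_renorm:
        warnings.warn(f"{n_renorm} sampled transition rows renormalized to "
                      "remain stochastic", stacklevel=2)

    wtp = np.asarray(config.wtp_grid, dtype=float)
    costs = np.column_stack([draws[lbl][:, 0] for lbl in labels])
    qalys = np.column_stack([draws[lbl][:, 1] for lbl in labels])
    ceac = np.empty((len(wtp), len(labels)))
    for i, lam in enumerate(wtp):
        winner = np.argmax(lam * qalys - costs, axis=1)
        ceac[i] = np.bincount(winner, minlength=len(labels)) / n
    ceac_frame = pd.DataFrame(ceac, index=pd.Index(wtp, name="wtp"),
                              columns=labels)
    return PSAResult(draws=draws, ceac=ceac_frame, wtp_grid=wtp,
                     n_renormalized=n_renorm, seed=config.seed)


def acceptability_report(psa: PSAResult, config: CEAConfig) -> pd.DataFrame:
    """Cost-effectiveness probabilities at the headline WTP thresholds.

    Linear interpolation covers thresholds between grid points.  The
    report flags the strategy preferred (highest acceptability) at the
    configured cost-effectiveness threshold.
    """
    labels = list(psa.ceac.columns)

    def prob_at(lam: float) -> np.ndarray:
        return np.array([
            np.interp(lam, psa.wtp_grid, psa.ceac[lbl].to_numpy())
            for lbl in labels])

    rows = {}
    for lam in config.headline_thresholds:
        rows[f"p_cost_effective_at_{int(lam)}"] = prob_at(lam)
    report = pd.DataFrame(rows, index=labels)
    at_threshold = prob_at(config.cost_effective_threshold)
    report["preferred_at_threshold"] = (
        np.arange(len(labels)) == int(np.argmax(at_threshold)))
    report.attrs["cost_effective_threshold"] = config.cost_effective_threshold
    report.index.name = "strategy"
    return report


# ---------------------------------------------------------------------------
# Plots (optional static figures)


def plot_ceac(psa: PSAResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for lbl in psa.ceac.columns:
        ax.plot(psa.wtp_grid, psa.ceac[lbl], marker="o", label=lbl)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(tornado: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = tornado.attrs.get("base_icer", np.nan)
    ordered = tornado.iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(ordered) + 1.5))
    for i, (_, row) in enumerate(ordered.iterrows()):
        lo, hi = sorted((row["icer_at_low"], row["icer_at_high"]))
        ax.barh(i, hi - lo, left=lo, color="#4878b0")
    ax.set_yticks(range(len(ordered)), ordered["parameter"])
    if np.isfinite(base):
        ax.axvline(base, color="k", lw=1, ls="--", label="base-case ICER")
        ax.legend()
    ax.set_xlabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
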