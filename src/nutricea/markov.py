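"""Three-state Markov cohort model: disease-free / relapse / death.

A cohort enters disease-free after chemoradiotherapy and each annual
cycle may stay stable, relapse, or die (of cancer or other causes).
State occupancy is propagated through a row-stochastic transition
matrix; quality-adjusted life-years and costs are accumulated per cycle
with annual discounting.  Rewards use state membership at cycle start
with no half-cycle correction, so results are bit-reproducible from the
specification alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "MarkovSpec",
    "CohortTrace",
    "StrategyResult",
    "MarkovResults",
    "MarkovCohortModel",
    "calibrate_annual_probs",
    "run_cohort",
    "life_expectancy",
    "get_param",
    "set_param",
]

STATES = ("disease_free", "relapse", "death")


class MarkovValidationError(ValueError):
    pass


@dataclass
class MarkovSpec:
    """Full parameterization of one strategy's decision model.

    ``transitions`` is a 3x3 row-stochastic matrix ordered as
    (disease_free, relapse, death), or an array of shape
    (horizon_cycles, 3, 3) for per-cycle matrices.  Utilities are QALY
    weights per year in each state; ``state_costs`` are annual USD per
    state; ``one_time_cost`` is the treatment cost charged undiscounted
    at cycle 0.
    """

    transitions: np.ndarray
    utilities: np.ndarray = field(
        default_factory=lambda: np.array([0.80, 0.53, 0.0]))
    state_costs: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    one_time_cost: float = 0.0
    discount_rate: float = 0.03
    cycle_length: float = 1.0
    horizon_cycles: int = 38
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    label: str = ""
    alive_stop_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.utilities = np.asarray(self.utilities, dtype=float)
        self.state_costs = np.asarray(self.state_costs, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution,
                                               dtype=float)
        self.validate()

    def validate(self) -> None:
        T = self.transitions
        if T.shape not in ((3, 3), (self.horizon_cycles, 3, 3)):
            raise MarkovValidationError(
                f"transitions must be 3x3 or (horizon, 3, 3); got {T.shape}")
        mats = T[None] if T.ndim == 2 else T
        if np.any(mats < -1e-12) or np.any(mats > 1 + 1e-12):
            raise MarkovValidationError("transition entries must lie in [0, 1]")
        if np.max(np.abs(mats.sum(axis=-1) - 1.0)) > 1e-12:
            raise MarkovValidationError("transition rows must sum to 1")
        if np.max(np.abs(mats[:, 2, :] - np.array([0.0, 0.0, 1.0]))) > 1e-12:
            raise MarkovValidationError("death must be absorbing")
        if np.any(self.utilities < 0) or np.any(self.utilities > 1):
            raise MarkovValidationError("utilities must lie in [0, 1]")
        if self.discount_rate < 0:
            raise MarkovValidationError("discount_rate must be >= 0")
        if self.cycle_length <= 0 or self.horizon_cycles <= 0:
            raise MarkovValidationError("cycle_length and horizon must be positive")
        init = self.initial_distribution
        if init.shape != (3,) or np.any(init < 0) or abs(init.sum() - 1) > 1e-9:
            raise MarkovValidationError("initial_distribution must be a "
                                        "probability 3-vector")

    def matrix_at(self, t: int) -> np.ndarray:
        return self.transitions if self.transitions.ndim == 2 else self.transitions[t]

    def copy(self) -> "MarkovSpec":
        return copy.deepcopy(self)


@dataclass
class CohortTrace:
    """Per-cycle occupancy fractions and discounted reward increments."""

    occupancy: np.ndarray                 # (cycles_run + 1, 3)
    discounted_cost_per_cycle: np.ndarray
    discounted_qaly_per_cycle: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.discounted_cost_per_cycle)
        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "cycle", np.arange(len(frame)))
        frame["discounted_cost"] = np.append(self.discounted_cost_per_cycle,
                                             np.nan)[: len(frame)]
        frame["discounted_qaly"] = np.append(self.discounted_qaly_per_cycle,
                                             np.nan)[: len(frame)]
        return frame


@dataclass(frozen=True)
class StrategyResult:
    """Total discounted cost (USD) and QALYs for one strategy."""

    strategy_label: str
    total_cost: float
    total_qalys: float


def calibrate_annual_probs(lrfs_1yr: float, os_1yr: float,
                           relapse_mortality: float,
                           background_mortality: float) -> np.ndarray:
    """Annual transition matrix from the observed 1-year rates.

    The probability of remaining disease-free equals the 1-year
    loco-regional progression-free survival; annual death from the
    disease-free state is the 1-year all-cause mortality (1 - OS)
    combined independently with background mortality and capped so that
    the row stays stochastic; relapse takes the remainder.  Death from
    the relapsed state combines the configured relapse mortality with
    background mortality.
    """
    for name, v in (("lrfs_1yr", lrfs_1yr), ("os_1yr", os_1yr),
                    ("relapse_mortality", relapse_mortality),
                    ("background_mortality", background_mortality)):
        if not 0.0 <= v <= 1.0:
            raise MarkovValidationError(f"{name} must be in [0, 1], got {v}")
    if lrfs_1yr <= 0 or os_1yr <= 0:
        raise MarkovValidationError("survival proportions must be positive")
    if lrfs_1yr > os_1yr:
        raise MarkovValidationError(
            "progression-free survival cannot exceed overall survival")

    def combine(p1: float, p2: float) -> float:
        return 1.0 - (1.0 - p1) * (1.0 - p2)

    p_df_death = min(combine(1.0 - os_1yr, background_mortality), 1.0 - lrfs_1yr)
    p_df_relapse = 1.0 - lrfs_1yr - p_df_death
    p_r_death = combine(relapse_mortality, background_mortality)
    return np.array([
        [lrfs_1yr, p_df_relapse, p_df_death],
        [0.0, 1.0 - p_r_death, p_r_death],
        [0.0, 0.0, 1.0],
    ])


def run_cohort(spec: MarkovSpec) -> tuple[CohortTrace, StrategyResult]:
    """Propagate the cohort and accumulate discounted rewards.

    Cycle-t rewards use occupancy at the start of cycle t discounted by
    (1 + r)^-t; the one-time treatment cost enters undiscounted at t=0.
    Propagation stops early once the alive fraction falls below
    ``spec.alive_stop_tol``.
    """
    spec.validate()
    occ = [spec.initial_distribution.copy()]
    costs, qalys = [], []
    r = spec.discount_rate
    for t in range(spec.horizon_cycles):
        state = occ[-1]
        if state[0] + state[1] < spec.alive_stop_tol:
            break
        disc = (1.0 + r) ** (-t)
        costs.append(float(state @ spec.state_costs * spec.cycle_length * disc))
        qalys.append(float(state @ spec.utilities * spec.cycle_length * disc))
        occ.append(state @ spec.matrix_at(t))
    costs_arr = np.asarray(costs)
    qalys_arr = np.asarray(qalys)
    trace = CohortTrace(np.vstack(occ), costs_arr, qalys_arr)
    result = StrategyResult(
        strategy_label=spec.label,
        total_cost=float(spec.one_time_cost + costs_arr.sum()),
        total_qalys=float(qalys_arr.sum()),
    )
    return trace, result


def life_expectancy(spec: MarkovSpec) -> float:
    """Undiscounted expected years alive over the model horizon."""
    undiscounted = replace(
        spec.copy(), discount_rate=0.0, alive_stop_tol=0.0)
    trace, _ = run_cohort(undiscounted)
    alive = 1.0 - trace.occupancy[:-1, 2]
    return float(alive.sum() * spec.cycle_length)


class MarkovCohortModel:
    """Model object wrapping a :class:`MarkovSpec`; ``run()`` returns results."""

    def __init__(self, spec: MarkovSpec):
        self.spec = spec

    @classmethod
    def from_trial_rates(cls, label: str, lrfs_1yr: float, os_1yr: float, *,
                         relapse_mortality: float = 0.5,
                         background_mortality: float = 0.01,
                         one_time_cost: float = 0.0,
                         **spec_kwargs) -> "MarkovCohortModel":
        """Build a strategy model from observed 1-year survival rates."""
        transitions = calibrate_annual_probs(
            lrfs_1yr, os_1yr, relapse_mortality, background_mortality)
        return cls(MarkovSpec(transitions=transitions, label=label,
                              one_time_cost=one_time_cost, **spec_kwargs))

    def run(self) -> "MarkovResults":
        trace, result = run_cohort(self.spec)
        return MarkovResults(self, trace, result)


class MarkovResults:
    """Results of one cohort run: trace, totals, summary table."""

    def __init__(self, model: MarkovCohortModel, trace: CohortTrace,
                 result: StrategyResult):
        self.model = model
        self.trace = trace
        self.result = result

    @property
    def total_cost(self) -> float:
        return self.result.total_cost

    @property
    def total_qalys(self) -> float:
        return self.result.total_qalys

    @property
    def life_expectancy(self) -> float:
        return life_expectancy(self.model.spec)

    def summary(self) -> pd.DataFrame:
        spec = self.model.spec
        rows = {
            "strategy": spec.label,
            "cycles_run": len(self.trace.discounted_cost_per_cycle),
            "total_cost_usd": round(self.total_cost, 2),
            "total_qalys": round(self.total_qalys, 4),
            "life_expectancy_years": round(self.life_expectancy, 4),
            "discount_rate": spec.discount_rate,
            "one_time_cost_usd": spec.one_time_cost,
        }
        return pd.DataFrame([rows]).set_index("strategy")


# ---------------------------------------------------------------------------
# Addressable parameters (used by sensitivity analyses)
#
# Paths: "one_time_cost", "discount_rate", "utilities.<state>",
# "state_costs.<state>", "transitions.<from>.<to>" where from != to.
# Setting an off-diagonal transition rebalances the row's stay
# probability; if the stay probability would become negative the row is
# renormalized and the spec's warning counter is incremented by the caller.


def _state_index(name: str) -> int:
    try:
        return STATES.index(name)
    except ValueError:
        raise KeyError(f"unknown state {name!r}") from None


def get_param(spec: MarkovSpec, path: str) -> float:
    parts = path.split(".")
    if path in ("one_time_cost", "discount_rate"):
        return float(getattr(spec, path))
    if parts[0] in ("utilities", "state_costs") and len(parts) == 2:
        return float(getattr(spec, parts[0])[_state_index(parts[1])])
    if parts[0] == "transitions" and len(parts) == 3:
        if spec.transitions.ndim != 2:
            raise KeyError("per-cycle transitions are not addressable by path")
        return float(spec.transitions[_state_index(parts[1]),
                                      _state_index(parts[2])])
    raise KeyError(f"unknown parameter path {path!r}")


def set_param(spec: MarkovSpec, path: str, value: float) -> tuple[MarkovSpec, bool]:
    """Return a new spec with ``path`` set to ``value``.

    The boolean flags whether a transition row had to be renormalized to
    stay within [0, 1].
    """
    new = spec.copy()
    parts = path.split(".")
    renormalized = False
    if path in ("one_time_cost", "discount_rate"):
        setattr(new, path, float(value))
    elif parts[0] in ("utilities", "state_costs") and len(parts) == 2:
        getattr(new, parts[0])[_state_index(parts[1])] = float(value)
        if parts[0] == "utilities":
            np.clip(new.utilities, 0.0, 1.0, out=new.utilities)
    elif parts[0] == "transitions" and len(parts) == 3:
        if new.transitions.ndim != 2:
            raise KeyError("per-cycle transitions are not addressable by path")
        i, j = _state_index(parts[1]), _state_index(parts[2])
        if i == j:
            raise KeyError("set off-diagonal transition probabilities; the "
                           "stay probability is the row remainder")
        if i == 2:
            raise KeyError("death is absorbing; its row is fixed")
        row = new.transitions[i].copy()
        row[j] = float(np.clip(value, 0.0, 1.0))
        off = row.sum() - row[i]
        if off > 1.0:
            row[:] = np.where(np.arange(3) == i, 0.0, row / off)
            renormalized = True
        row[i] = 1.0 - (row.sum() - row[i])
        new.transitions[i] = row
    else:
        raise KeyError(f"unknown parameter path {path!r}")
    new.validate()
    return new, renormalized
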