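import numpy as np
import pytest

from nutricea.cohort import PatientRecord
from nutricea.config import default_config, profiles_from_config, \
    strategy_specs_from_config
from nutricea.markov import MarkovSpec, StrategyResult


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def profiles(config):
    return profiles_from_config(config)


@pytest.fixture(scope="session")
def peg_profile(profiles):
    return next(p for p in profiles if p.arm_label == "PEG")


@pytest.fixture(scope="session")
def strategy_specs(config):
    return strategy_specs_from_config(config)


def make_records(arm, n, **overrides):
    """Minimal patient records for tests that only touch a few fields."""
    defaults = dict(age=60.0, sex="male", stage="III", ecog="0-1",
                    baseline_weight=58.0, weight_change_pct=-2.0,
                    weight_category="loss", albumin_ge35=True, crp_lt15=True,
                    lymph_ge1=False, response="CR", lrfs_time=1.0,
                    lrfs_event=False, os_time=1.0, os_event=False,
                    costs={"total": 100.0}, hospital_days=10.0)
    records = []
    for i in range(n):
        kwargs = dict(defaults)
        for key, value in overrides.items():
            kwargs[key] = value[i] if isinstance(value, (list, tuple)) else value
        records.append(PatientRecord(subject_id=f"{arm}-{i:04d}",
                                     arm_label=arm, **kwargs))
    return records


@pytest.fixture(scope="session")
def record_factory():
    return make_records


# ---------------------------------------------------------------------------
# Independent oracles


def nmb_frontier_oracle(results):
    """Frontier membership via a brute-force NMB sweep.

    A strategy lies on the efficiency frontier iff it uniquely maximizes
    net monetary benefit on some open interval of willingness-to-pay.
    Candidate breakpoints are all pairwise incremental ratios; the
    maximizer is evaluated at midpoints between consecutive breakpoints
    (plus 0 and a point beyond the largest breakpoint), which determines
    membership exactly for generic (tie-free) inputs.
    """
    breakpoints = {0.0}
    for a in results:
        for b in results:
            dq = b.total_qalys - a.total_qalys
            if dq != 0:
                lam = (b.total_cost - a.total_cost) / dq
                if lam > 0:
                    breakpoints.add(lam)
    grid = sorted(breakpoints)
    probes = [0.0]
    probes += [(x + y) / 2 for x, y in zip(grid, grid[1:])]
    probes.append(grid[-1] * 2 + 1.0)
    winners = set()
    for lam in probes:
        nmbs = [lam * r.total_qalys - r.total_cost for r in results]
        best = max(nmbs)
        top = [r.strategy_label for r, v in zip(results, nmbs) if v == best]
        if len(top) == 1:
            winners.add(top[0])
    return winners


@pytest.fixture(scope="session")
def frontier_oracle():
    return nmb_frontier_oracle


def microsimulate(spec: MarkovSpec, n_paths: int, seed: int):
    """Per-individual Monte-Carlo rollout of a time-homogeneous spec.

    Returns mean cost and QALYs with their standard errors; an
    independent check of the deterministic cohort recursion.
    """
    rng = np.random.default_rng(seed)
    P = spec.transitions
    assert P.ndim == 2
    states = rng.choice(3, size=n_paths, p=spec.initial_distribution)
    cost = np.full(n_paths, float(spec.one_time_cost))
    qaly = np.zeros(n_paths)
    for t in range(spec.horizon_cycles):
        disc = (1.0 + spec.discount_rate) ** (-t)
        cost += spec.state_costs[states] * spec.cycle_length * disc
        qaly += spec.utilities[states] * spec.cycle_length * disc
        nxt = np.empty(n_paths, dtype=int)
        for s in range(3):
            mask = states == s
            if mask.any():
                nxt[mask] = rng.choice(3, size=int(mask.sum()), p=P[s])
        states = nxt
    return ((cost.mean(), cost.std(ddof=1) / np.sqrt(n_paths)),
            (qaly.mean(), qaly.std(ddof=1) / np.sqrt(n_paths)))


@pytest.fixture(scope="session")
def microsim_oracle():
    return microsimulate
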