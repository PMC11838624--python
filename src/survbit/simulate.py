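"""Seeded stochastic simulation of the hidden chain, detector and policy.

This is the empirical oracle for the exact losses: simulate the two-state
chain from stationarity, emit one observation bit per step, apply a decision
table to the trailing observation window, and accrue normalized per-step
costs (``K`` on intervention, 1 on an unmitigated abnormal step, plus the
surveillance cost ``S[n]`` on every scored step).  It doubles as the
synthetic-data generator for the test suite: :func:`random_bundle` and
:func:`random_strategy` draw parameter sets from the intended operating
regime.

Standard errors reported by :func:`empirical_cost` are naive i.i.d. ones;
serial correlation of the chain makes them optimistic, so oracle comparisons
should use a generous (5 sigma) band.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import ModelBundle, ModelError, Strategy, CostModel, DetectorModel, SystemModel
from .models import stationary_abnormal_prob

__all__ = [
    "SimulationRun",
    "simulate_chain",
    "apply_strategy",
    "run_policy",
    "empirical_cost",
    "write_run",
    "read_run",
    "random_bundle",
    "random_strategy",
]


@dataclass(frozen=True)
class SimulationRun:
    """One simulated trajectory: hidden states, observations, actions, costs.

    ``costs`` holds the realized per-step cost including the surveillance
    cost on scored steps; steps before ``scored_from`` (insufficient
    observation history) take action 0, cost 0, and are excluded from
    scoring.  ``states`` is ``None`` for runs read back from files written
    without the hidden-state column.
    """

    T: int
    seed: Optional[int]
    states: Optional[np.ndarray]
    observations: np.ndarray
    actions: np.ndarray
    costs: np.ndarray
    n: Optional[int] = None

    @property
    def scored_from(self) -> int:
        if self.n is None:
            return 0
        return max(self.n - 1, 0)


def simulate_chain(T: int, bundle: ModelBundle, seed: int,
                   initial_state: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``T`` steps of the hidden chain and its observations.

    The initial state is drawn from the stationary distribution unless
    ``initial_state`` forces it, making the steady-state assumption exact
    from the first step.  A single generator seeded with ``seed`` drives
    both state transitions and emissions, so runs are fully reproducible.
    """
    if T < 1:
        raise ModelError(f"T must be >= 1, got {T}")
    sys_, det = bundle.system, bundle.detector
    rng = np.random.default_rng(seed)
    u = rng.random(T)
    states = np.empty(T, dtype=np.int8)
    if initial_state is None:
        s = 1 if u[0] < stationary_abnormal_prob(sys_) else 0
    else:
        if initial_state not in (0, 1):
            raise ModelError(f"initial_state must be 0 or 1, got {initial_state!r}")
        s = initial_state
    states[0] = s
    q01, q11 = sys_.q01, sys_.q11
    ul = u.tolist()  # python floats: ~3x faster inner loop than ndarray indexing
    for t in range(1, T):
        s = (1 if ul[t] < q11 else 0) if s else (1 if ul[t] < q01 else 0)
        states[t] = s
    p1 = np.where(states == 1, det.p11, det.p01)
    observations = (rng.random(T) < p1).astype(np.int8)
    return states, observations


def apply_strategy(observations: np.ndarray, strategy: Strategy) -> np.ndarray:
    """Actions from sliding the decision table over the observation stream.

    The action at step t (0-indexed, t >= n-1) looks up the window
    ``observations[t-n+1 .. t]`` oldest bit first; earlier steps have no
    full window and take action 0.
    """
    obs = np.asarray(observations, dtype=np.int64)
    T = obs.shape[0]
    n = strategy.n
    actions = np.zeros(T, dtype=np.int8)
    if n == 0:
        actions[:] = strategy.table[0]
        return actions
    if T < n:
        return actions
    weights = 2 ** np.arange(n - 1, -1, -1)  # oldest bit is most significant
    windows = np.lib.stride_tricks.sliding_window_view(obs, n)
    idx = windows @ weights
    table = np.asarray(strategy.table, dtype=np.int8)
    actions[n - 1:] = table[idx]
    return actions


def run_policy(strategy: Strategy, bundle: ModelBundle, T: int, seed: int) -> SimulationRun:
    """Simulate a full surveillance-and-intervention run under ``strategy``."""
    s_n = bundle.costs.surveillance_cost(strategy.n)
    states, observations = simulate_chain(T, bundle, seed)
    actions = apply_strategy(observations, strategy)
    K = bundle.costs.K
    costs = np.where(actions == 1, K, states.astype(float)) + s_n
    start = max(strategy.n - 1, 0)
    costs[:start] = 0.0
    return SimulationRun(T=T, seed=seed, states=states, observations=observations,
                         actions=actions, costs=costs, n=strategy.n)


def empirical_cost(run: SimulationRun) -> tuple[float, float]:
    """Mean cost per scored step and its naive standard error."""
    scored = run.costs[run.scored_from:]
    m = scored.shape[0]
    if m == 0:
        raise ModelError("no scored steps: run shorter than the strategy depth")
    mean = float(scored.mean())
    stderr = float(scored.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan")
    return mean, stderr


def write_run(run: SimulationRun, path, include_state: bool = True) -> None:
    """Write a run as CSV (columns ``t,state,obs,action,cost``; t is 1-indexed).

    With ``include_state=False`` the hidden-state column is omitted,
    emulating what a real deployment would record.
    """
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            if include_state:
                writer.writerow(["t", "state", "obs", "action", "cost"])
                for t in range(run.T):
                    writer.writerow([t + 1, int(run.states[t]), int(run.observations[t]),
                                     int(run.actions[t]), repr(float(run.costs[t]))])
            else:
                writer.writerow(["t", "obs", "action", "cost"])
                for t in range(run.T):
                    writer.writerow([t + 1, int(run.observations[t]),
                                     int(run.actions[t]), repr(float(run.costs[t]))])
    except OSError as exc:
        raise OSError(f"cannot write run to {path}: {exc}") from exc


def read_run(path) -> SimulationRun:
    """Read a run written by :func:`write_run`; hidden states may be absent."""
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            rows = list(reader)
    except OSError as exc:
        raise OSError(f"cannot read run from {path}: {exc}") from exc
    has_state = "state" in header
    cols = {name: i for i, name in enumerate(header)}
    T = len(rows)
    states = np.empty(T, dtype=np.int8) if has_state else None
    observations = np.empty(T, dtype=np.int8)
    actions = np.empty(T, dtype=np.int8)
    costs = np.empty(T, dtype=float)
    for t, row in enumerate(rows):
        if has_state:
            states[t] = int(row[cols["state"]])
        observations[t] = int(row[cols["obs"]])
        actions[t] = int(row[cols["action"]])
        costs[t] = float(row[cols["cost"]])
    return SimulationRun(T=T, seed=None, states=states, observations=observations,
                         actions=actions, costs=costs, n=None)


# ---------------------------------------------------------------------
# synthetic parameter / strategy draws for testing
# ---------------------------------------------------------------------

def random_bundle(rng: np.random.Generator, max_depth: int = 4,
                  calibrated: bool = True) -> ModelBundle:
    """Draw a random parameter set from the intended operating regime.

    With ``calibrated=True`` (default) the detector satisfies
    ``p01 < 1/2 < p11`` — strictly stronger than the bare informativeness
    condition ``p11 > p01``, and required for the observation-dominance
    ordering (intervening on 1s beats intervening on 0s) to hold for every
    ``K``.  With ``calibrated=False`` only ``p11 > p01`` is guaranteed.
    """
    q01 = rng.uniform(0.02, 0.48)
    q10 = rng.uniform(0.02, 0.48)
    if calibrated:
        p01 = rng.uniform(0.02, 0.48)
        p11 = rng.uniform(0.52, 0.98)
    else:
        p01, p11 = np.sort(rng.uniform(0.01, 0.99, size=2))
    K = rng.uniform(0.05, 0.95)
    increments = rng.uniform(0.001, 0.02, size=max_depth)
    S = (0.0, *np.cumsum(increments))
    return ModelBundle(system=SystemModel(q01=q01, q10=q10),
                       detector=DetectorModel(p01=p01, p11=p11),
                       costs=CostModel(K=K, S=S))


def random_strategy(rng: np.random.Generator, n: int) -> Strategy:
    """Uniformly random depth-``n`` decision table."""
    return Strategy(n, tuple(int(b) for b in rng.integers(0, 2, size=2 ** n)))
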