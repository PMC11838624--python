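"""Optimal strategy construction, protocol selection and phase diagrams.

The per-depth optimum thresholds the Δ statistic: intervene on history ``b``
exactly when Δ(b) > 0 (a Δ(b) = 0 tie maps to no action).  Protocol
selection compares the no-surveillance baselines against the per-depth
optima up to a maximum depth; phase diagrams classify each point of a 2-D
parameter grid by the winning protocol label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .inference import delta_table
from .loss import LossValue, expected_loss
from .models import (
    ConfigurationError,
    CostModel,
    DetectorModel,
    ModelBundle,
    ModelError,
    Strategy,
    SystemModel,
)

__all__ = [
    "ProtocolChoice",
    "AxisSpec",
    "PhaseGrid",
    "optimal_strategy",
    "brute_force_optimal",
    "select_protocol",
    "phase_diagram",
    "with_override",
]

_BRUTE_FORCE_MAX_N = 4


def _rank_key(item: tuple[Strategy, LossValue]) -> tuple:
    """Ascending loss; ties prefer smaller depth, fewer interventions, then
    the lexicographically smallest table string.

    Losses are quantized at 1e-12 so that mathematically exact ties (e.g.
    the all-one table at depth n vs the unconditional baseline when S[n]=0,
    identical up to float rounding of the delta sum) resolve by the stated
    tie rule instead of by accumulated rounding noise.
    """
    strategy, lv = item
    return (round(lv.value, 12), strategy.n, strategy.ones, strategy.table_string)


def optimal_strategy(n: int, bundle: ModelBundle) -> Strategy:
    """Depth-``n`` loss minimizer: intervene on ``b`` iff Δ(b) > 0."""
    if n < 1:
        raise ModelError(f"optimal_strategy requires depth >= 1, got {n}")
    deltas = delta_table(n, bundle)
    return Strategy(n, tuple(int(d > 0) for d in deltas))


def brute_force_optimal(n: int, bundle: ModelBundle) -> Strategy:
    """Exhaustive argmin over all 2^(2^n) depth-``n`` decision tables.

    Test oracle for :func:`optimal_strategy`; refuses n > 4 (65,536 tables).
    Ties are resolved with the same ordering as protocol ranking.
    """
    if n < 1:
        raise ModelError(f"brute_force_optimal requires depth >= 1, got {n}")
    if n > _BRUTE_FORCE_MAX_N:
        raise ModelError(
            f"brute-force enumeration refused for n={n} (> {_BRUTE_FORCE_MAX_N}): "
            f"2^(2^{n}) strategies"
        )
    candidates = []
    for table in itertools.product((0, 1), repeat=2 ** n):
        strategy = Strategy(n, table)
        candidates.append((strategy, expected_loss(strategy, bundle)))
    return min(candidates, key=_rank_key)[0]


@dataclass(frozen=True)
class ProtocolChoice:
    """Winning strategy plus the full ranking of considered alternatives."""

    chosen: Strategy
    loss: LossValue
    ranked: tuple[tuple[Strategy, LossValue], ...]

    def to_dict(self) -> dict:
        return {
            "chosen": {
                "label": self.chosen.label,
                "strategy": self.chosen.to_dict(),
                "loss": self.loss.value,
                "S_n": self.loss.depth_cost,
            },
            "ranked": [
                {"label": s.label, "n": s.n, "table": s.table_string, "loss": lv.value}
                for s, lv in self.ranked
            ],
        }


def select_protocol(max_n: int, bundle: ModelBundle) -> ProtocolChoice:
    """Pick the minimum-loss protocol among never, always, and the per-depth
    Δ-threshold optima for n = 1..``max_n``."""
    if max_n < 0:
        raise ConfigurationError(f"max_n must be nonnegative, got {max_n}")
    bundle.costs.surveillance_cost(max_n)  # fail fast on missing S entries
    candidates: list[Strategy] = [Strategy.never(), Strategy.always()]
    candidates += [optimal_strategy(n, bundle) for n in range(1, max_n + 1)]
    ranked = sorted(((s, expected_loss(s, bundle)) for s in candidates), key=_rank_key)
    chosen, loss = ranked[0]
    return ProtocolChoice(chosen=chosen, loss=loss, ranked=tuple(ranked))


# ---------------------------------------------------------------------
# parameter overrides and phase diagrams
# ---------------------------------------------------------------------

def with_override(bundle: ModelBundle, name: str, value: float) -> ModelBundle:
    """Copy of ``bundle`` with one named parameter replaced.

    Supported names: q01, q10, p01, p11, K, and S1, S2, ... (surveillance
    cost at the given depth; the S list is extended with the new value
    repeated if it is shorter than required).
    """
    if name in ("q01", "q10"):
        return replace(bundle, system=replace(bundle.system, **{name: value}))
    if name in ("p01", "p11"):
        return replace(bundle, detector=replace(bundle.detector, **{name: value}))
    if name == "K":
        return replace(bundle, costs=replace(bundle.costs, K=value))
    if name.startswith("S") and name[1:].isdigit():
        depth = int(name[1:])
        if depth < 1:
            raise ConfigurationError("S0 is fixed at 0 and cannot be overridden")
        S = list(bundle.costs.S)
        while len(S) <= depth:
            S.append(value)
        S[depth] = value
        return replace(bundle, costs=replace(bundle.costs, S=tuple(S)))
    raise ConfigurationError(f"unknown parameter {name!r} for override")


@dataclass(frozen=True)
class AxisSpec:
    """One phase-diagram axis: parameter name and an inclusive linear range."""

    name: str
    start: float
    stop: float
    num: int

    def __post_init__(self) -> None:
        if self.num < 1:
            raise ConfigurationError(f"axis needs at least one point, got num={self.num}")
        if self.stop < self.start:
            raise ConfigurationError(
                f"axis range must be nondecreasing, got {self.start}:{self.stop}"
            )

    @classmethod
    def parse(cls, text: str) -> "AxisSpec":
        """Parse ``"name:min:max:steps"`` (inclusive endpoints)."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ConfigurationError(f"axis spec must be name:min:max:steps, got {text!r}")
        name, start, stop, num = parts
        try:
            return cls(name=name, start=float(start), stop=float(stop), num=int(num))
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse axis spec {text!r}") from exc

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)

    def to_dict(self) -> dict:
        return {"name": self.name, "start": self.start, "stop": self.stop, "num": self.num}


@dataclass(frozen=True)
class PhaseGrid:
    """Grid of winning-protocol labels over two swept parameters.

    ``labels[i][j]`` is the label at ``axis2.values[i]`` (rows) and
    ``axis1.values[j]`` (columns).
    """

    axis1: AxisSpec
    axis2: AxisSpec
    labels: tuple[tuple[str, ...], ...]
    max_n: int

    def cells(self) -> Iterator[tuple[int, int, float, float, str]]:
        v1, v2 = self.axis1.values, self.axis2.values
        for i, row in enumerate(self.labels):
            for j, label in enumerate(row):
                yield i, j, v1[j], v2[i], label

    def to_tsv(self) -> str:
        lines = ["\t".join(row) for row in self.labels]
        return "\n".join(lines) + "\n"

    def metadata(self) -> dict:
        return {
            "axis1": self.axis1.to_dict(),
            "axis2": self.axis2.to_dict(),
            "max_n": self.max_n,
            "layout": "rows are axis2 values (first row = axis2 start), columns are axis1 values",
            "labels": sorted({label for row in self.labels for label in row}),
        }


def phase_diagram(axis1: AxisSpec, axis2: AxisSpec, bundle: ModelBundle,
                  max_n: int) -> PhaseGrid:
    """Classify each grid point by the label of its winning protocol.

    Classification is pointwise — every cell is an independent
    :func:`select_protocol` run, so re-evaluating any cell reproduces its
    label exactly.
    """
    v1, v2 = axis1.values, axis2.values
    rows = []
    for y in v2:
        bundle_y = with_override(bundle, axis2.name, float(y))
        row = []
        for x in v1:
            cell = with_override(bundle_y, axis1.name, float(x))
            row.append(select_protocol(max_n, cell).chosen.label)
        rows.append(tuple(row))
    return PhaseGrid(axis1=axis1, axis2=axis2, labels=tuple(rows), max_n=max_n)
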