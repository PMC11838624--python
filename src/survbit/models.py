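"""Core domain types for the binary surveillance decision model.

The monitored system is a hidden two-state Markov chain (0 = normal,
1 = abnormal).  A binary detector emits one bit per time step, Bernoulli
conditional on the same-time hidden state.  Costs are dimensionless,
normalized by the cost of one unmitigated abnormal step: ``K`` is the
per-step intervention cost and ``S[n]`` the per-step cost of running
surveillance at observation-window depth ``n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ModelError",
    "ConfigurationError",
    "SystemModel",
    "DetectorModel",
    "CostModel",
    "Strategy",
    "ModelBundle",
    "stationary_abnormal_prob",
    "propagate_prior",
    "validate",
]

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised when model parameters are unusable (out of range, degenerate)."""


class ConfigurationError(ModelError):
    """Raised when a configuration is incomplete or inconsistent."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ModelError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class SystemModel:
    """Transition probabilities of the hidden two-state chain.

    Parameters
    ----------
    q01:
        Per-step probability of switching normal -> abnormal.
    q10:
        Per-step probability of switching abnormal -> normal.

    The complements ``q00 = 1 - q01`` and ``q11 = 1 - q10`` are derived,
    never stored, so row normalization is exact by construction.
    """

    q01: float
    q10: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "q01", _check_prob("q01", self.q01))
        object.__setattr__(self, "q10", _check_prob("q10", self.q10))

    @property
    def q00(self) -> float:
        return 1.0 - self.q01

    @property
    def q11(self) -> float:
        return 1.0 - self.q10

    def transition(self, src: int, dst: int) -> float:
        """P(state t+1 = ``dst`` | state t = ``src``)."""
        if src == 0:
            return self.q01 if dst == 1 else self.q00
        return self.q11 if dst == 1 else self.q10


@dataclass(frozen=True)
class DetectorModel:
    """Emission probabilities of the binary detector.

    ``p01`` is P(observe 1 | normal); ``p11`` is P(observe 1 | abnormal).
    Complements ``p00`` and ``p10`` are derived.
    """

    p01: float
    p11: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p01", _check_prob("p01", self.p01))
        object.__setattr__(self, "p11", _check_prob("p11", self.p11))

    @property
    def p00(self) -> float:
        return 1.0 - self.p01

    @property
    def p10(self) -> float:
        return 1.0 - self.p11

    def emission(self, state: int, bit: int) -> float:
        """P(observe ``bit`` | hidden ``state``)."""
        p1 = self.p11 if state == 1 else self.p01
        return p1 if bit == 1 else 1.0 - p1


@dataclass(frozen=True)
class CostModel:
    """Normalized costs: intervention cost ``K`` and surveillance costs ``S``.

    ``S`` is indexed by surveillance depth; ``S[0]`` must be 0 (no
    surveillance is free).  Raw costs ``(k, c, s_n)`` can be supplied via
    :meth:`from_raw`, which divides through by ``c`` immediately.
    """

    K: float
    S: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        K = float(self.K)
        if K < 0:
            raise ModelError(f"K must be nonnegative, got {K!r}")
        S = tuple(float(s) for s in self.S)
        if not S:
            raise ModelError("S must contain at least the depth-0 entry")
        if S[0] != 0.0:
            raise ModelError(f"S[0] must be 0 (no surveillance costs nothing), got {S[0]!r}")
        if any(s < 0 for s in S):
            raise ModelError("surveillance costs must be nonnegative")
        for n in range(1, len(S)):
            if S[n] < S[n - 1]:
                logger.warning("surveillance cost decreases with depth: S[%d]=%g < S[%d]=%g",
                               n, S[n], n - 1, S[n - 1])
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "S", S)

    @classmethod
    def from_raw(cls, k: float, c: float, s: Sequence[float] = (0.0,)) -> "CostModel":
        """Build from raw costs, normalizing everything by the abnormality cost ``c``."""
        if c <= 0:
            raise ModelError(f"abnormality cost c must be positive, got {c!r}")
        return cls(K=k / c, S=tuple(si / c for si in s))

    def surveillance_cost(self, n: int) -> float:
        """Per-step surveillance cost ``S[n]`` at depth ``n``."""
        if n < 0:
            raise ConfigurationError(f"surveillance depth must be nonnegative, got {n}")
        if n >= len(self.S):
            raise ConfigurationError(
                f"no surveillance cost configured for depth {n}: S has entries for n <= {len(self.S) - 1}"
            )
        return self.S[n]

    @property
    def max_depth(self) -> int:
        return len(self.S) - 1


@dataclass(frozen=True)
class Strategy:
    """A surveillance depth ``n`` plus a full decision table.

    ``table`` has one entry per length-``n`` observation history, indexed by
    the integer whose binary expansion is the history written oldest bit
    first (so the most recent observation is the least significant bit).
    ``table[i] = 1`` means intervene whenever that history is observed.
    For ``n = 0`` the table holds the single unconditional action.
    """

    n: int
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        n = int(self.n)
        if n < 0:
            raise ModelError(f"strategy depth must be nonnegative, got {n}")
        table = tuple(int(a) for a in self.table)
        if len(table) != 2 ** n:
            raise ModelError(
                f"table must have {2 ** n} entries for depth {n}, got {len(table)}"
            )
        if any(a not in (0, 1) for a in table):
            raise ModelError("table entries must be 0 or 1")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "table", table)

    # -- constructors --------------------------------------------------

    @classmethod
    def all_zero(cls, n: int) -> "Strategy":
        return cls(n, (0,) * 2 ** n)

    @classmethod
    def all_one(cls, n: int) -> "Strategy":
        return cls(n, (1,) * 2 ** n)

    @classmethod
    def never(cls) -> "Strategy":
        return cls(0, (0,))

    @classmethod
    def always(cls) -> "Strategy":
        return cls(0, (1,))

    @classmethod
    def from_dict(cls, data: Mapping) -> "Strategy":
        """Parse ``{"n": int, "table": {"<history>": 0|1}}`` (histories oldest bit first)."""
        n = int(data["n"])
        raw = data["table"]
        table = [0] * 2 ** n
        seen = set()
        for hist, action in raw.items():
            hist = str(hist)
            if len(hist) != n or any(ch not in "01" for ch in hist):
                raise ModelError(f"invalid history key {hist!r} for depth {n}")
            idx = int(hist, 2) if n else 0
            table[idx] = int(action)
            seen.add(idx)
        if len(seen) != 2 ** n:
            raise ModelError(f"table must have {2 ** n} entries for depth {n}, got {len(seen)}")
        return cls(n, tuple(table))

    @classmethod
    def from_spec(cls, spec: str) -> "Strategy":
        """Parse an inline spec like ``"n=2:0011"`` (table in history-index order).

        ``"never"`` and ``"always"`` are accepted as depth-0 shorthands.
        """
        spec = spec.strip()
        if spec == "never":
            return cls.never()
        if spec == "always":
            return cls.always()
        try:
            head, bits = spec.split(":", 1)
            n = int(head.removeprefix("n="))
        except ValueError as exc:
            raise ModelError(f"cannot parse strategy spec {spec!r}") from exc
        if any(ch not in "01" for ch in bits):
            raise ModelError(f"strategy table must be a bit string, got {bits!r}")
        return cls(n, tuple(int(b) for b in bits))

    # -- accessors -----------------------------------------------------

    def history_string(self, index: int) -> str:
        """History (oldest bit first) for a table index."""
        return format(index, f"0{self.n}b") if self.n else ""

    def action(self, history: Sequence[int]) -> int:
        """Action for an explicit history (oldest -> most recent)."""
        if len(history) != self.n:
            raise ModelError(f"history length {len(history)} != strategy depth {self.n}")
        idx = 0
        for b in history:
            idx = (idx << 1) | int(b)
        return self.table[idx]

    @property
    def ones(self) -> int:
        return sum(self.table)

    @property
    def table_string(self) -> str:
        return "".join(str(a) for a in self.table)

    @property
    def label(self) -> str:
        """Human-readable identifier (``never``/``always`` at depth 0)."""
        if self.n == 0:
            return "always" if self.table[0] else "never"
        return f"n={self.n}:{self.table_string}"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "table": {self.history_string(i): a for i, a in enumerate(self.table)},
        }


@dataclass(frozen=True)
class ModelBundle:
    """Aggregate of system, detector and cost parameters."""

    system: SystemModel
    detector: DetectorModel
    costs: CostModel

    def describe(self) -> dict:
        return {
            "q01": self.system.q01,
            "q10": self.system.q10,
            "p01": self.detector.p01,
            "p11": self.detector.p11,
            "K": self.costs.K,
            "S": list(self.costs.S),
        }


# ---------------------------------------------------------------------
# stationary / prior computations
# ---------------------------------------------------------------------

def stationary_abnormal_prob(system: SystemModel) -> float:
    """Stationary probability ``a1 = q01 / (q01 + q10)`` of the abnormal state."""
    denom = system.q01 + system.q10
    if denom == 0.0:
        raise ModelError("q01 = q10 = 0: stationary distribution is undefined")
    return system.q01 / denom


def stationary_distribution(system: SystemModel) -> tuple[float, float]:
    """``(a0, a1)`` with ``a0 + a1 = 1`` exactly."""
    a1 = stationary_abnormal_prob(system)
    return 1.0 - a1, a1


def propagate_prior(a1_t: float, system: SystemModel) -> float:
    """One-step update of the abnormal-state probability.

    Returns ``a1_t * (1 - q10) + (1 - a1_t) * q01``; the stationary value is
    the unique fixed point of this affine map.
    """
    a1_t = _check_prob("a1_t", a1_t)
    return a1_t * (1.0 - system.q10) + (1.0 - a1_t) * system.q01


def validate(bundle: ModelBundle, strict: bool = True) -> list[str]:
    """Report modelling-assumption violations; an empty list means valid.

    Lenient mode only confirms probability ranges and normalization (which
    dataclass construction already enforces, so it mostly guards hand-built
    objects).  Strict mode additionally checks the intended operating
    regime: persistent states (``q00 > q01``, ``q11 > q10``), an informative
    detector (``p11 > p01``), a worthwhile intervention (``0 < K < 1``) and
    reachable states (``0 < q01, q10 < 1``).
    """
    sys_, det, costs = bundle.system, bundle.detector, bundle.costs
    violations: list[str] = []
    for name, value in (("q01", sys_.q01), ("q10", sys_.q10),
                        ("p01", det.p01), ("p11", det.p11)):
        if not 0.0 <= value <= 1.0:
            violations.append(f"{name} out of [0, 1]")
    if costs.S and costs.S[0] != 0.0:
        violations.append("S[0] != 0")
    if any(s < 0 for s in costs.S):
        violations.append("S[n] < 0")
    if not strict:
        return violations
    if not 0.0 < sys_.q01 < 1.0 or not 0.0 < sys_.q10 < 1.0:
        violations.append("0 < q01 < 1 and 0 < q10 < 1 (both states reachable)")
    if sys_.q01 >= 0.5:
        violations.append("q00 > q01")
    if sys_.q10 >= 0.5:
        violations.append("q11 > q10")
    if not det.p11 > det.p01:
        violations.append("p11 > p01")
    if not 0.0 < costs.K < 1.0:
        violations.append("K < 1" if costs.K >= 1.0 else "K > 0")
    return violations
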