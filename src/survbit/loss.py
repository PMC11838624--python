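"""Exact expected cost per unit time of surveillance-and-intervention strategies.

For a depth-``n`` strategy with decision table ``Y``,

    L_n(Y) = a1 + S[n] - sum over histories b with Y(b) = 1 of Δ(b),

a steady-state per-step rate in units of the abnormality cost.  Depth 0 is
the no-surveillance baseline: always intervening costs ``K`` per step, never
intervening costs ``a1`` per step.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inference import delta_table
from .models import ModelBundle, ModelError, Strategy, stationary_abnormal_prob

__all__ = ["LossValue", "loss_no_surveillance", "expected_loss"]


@dataclass(frozen=True)
class LossValue:
    """A strategy together with its exact expected cost per unit time."""

    value: float
    strategy: Strategy
    depth_cost: float

    def __float__(self) -> float:
        return self.value


def loss_no_surveillance(action: int, bundle: ModelBundle) -> LossValue:
    """Baseline loss with no surveillance: ``K`` if always intervening, ``a1`` if never."""
    if action not in (0, 1):
        raise ModelError(f"action must be 0 or 1, got {action!r}")
    if action == 1:
        value = bundle.costs.K
        strategy = Strategy.always()
    else:
        value = stationary_abnormal_prob(bundle.system)
        strategy = Strategy.never()
    return LossValue(value=value, strategy=strategy, depth_cost=bundle.costs.surveillance_cost(0))


def expected_loss(strategy: Strategy, bundle: ModelBundle) -> LossValue:
    """Exact expected cost per unit time of ``strategy`` under ``bundle``."""
    s_n = bundle.costs.surveillance_cost(strategy.n)
    if strategy.n == 0:
        base = loss_no_surveillance(strategy.table[0], bundle)
        return LossValue(value=base.value + s_n, strategy=strategy, depth_cost=s_n)
    a1 = stationary_abnormal_prob(bundle.system)
    deltas = delta_table(strategy.n, bundle)
    gain = sum(d for d, y in zip(deltas, strategy.table) if y)
    return LossValue(value=float(a1 + s_n - gain), strategy=strategy, depth_cost=s_n)
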