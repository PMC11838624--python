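"""Exact probabilistic computations over observation histories.

Joint history/state probabilities are computed by forward filtering over the
hidden chain started at stationarity: two running values (one per current
hidden state), linear in the history length.  The Δ statistic for a history
``b`` is the expected per-step cost of inaction minus intervention,

    Δ(b) = (1 - K) * P(b, abnormal) - K * P(b, normal),

whose sign determines the optimal action for that history.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .models import ModelBundle, ModelError, stationary_distribution

__all__ = [
    "parse_history",
    "joint_probs",
    "joint_prob",
    "history_prob",
    "posterior_abnormal",
    "delta",
    "delta_table",
    "joint_table",
    "tabulate",
]


def parse_history(text: str) -> tuple[int, ...]:
    """Parse a bit string (oldest observation first) into a history tuple."""
    text = text.strip()
    if not text or any(ch not in "01" for ch in text):
        raise ModelError(f"history must be a nonempty bit string, got {text!r}")
    return tuple(int(ch) for ch in text)


def _coerce_history(history: Sequence[int]) -> tuple[int, ...]:
    if isinstance(history, str):
        return parse_history(history)
    bits = tuple(int(b) for b in history)
    if not bits:
        raise ModelError("history must contain at least one observation")
    if any(b not in (0, 1) for b in bits):
        raise ModelError(f"history bits must be 0 or 1, got {history!r}")
    return bits


def joint_probs(history: Sequence[int], bundle: ModelBundle) -> tuple[float, float]:
    """``(P(history, final normal), P(history, final abnormal))``.

    The hidden state at the first observation is drawn from the stationary
    distribution; the final state refers to the time of the last observation.
    """
    bits = _coerce_history(history)
    a0, a1 = stationary_distribution(bundle.system)
    det, sys_ = bundle.detector, bundle.system
    f0 = a0 * det.emission(0, bits[0])
    f1 = a1 * det.emission(1, bits[0])
    for b in bits[1:]:
        f0, f1 = (
            (f0 * sys_.q00 + f1 * sys_.q10) * det.emission(0, b),
            (f0 * sys_.q01 + f1 * sys_.q11) * det.emission(1, b),
        )
    return f0, f1


def joint_prob(history: Sequence[int], final_state: int, bundle: ModelBundle) -> float:
    """Probability of observing ``history`` with the given final hidden state."""
    if final_state not in (0, 1):
        raise ModelError(f"final_state must be 0 (normal) or 1 (abnormal), got {final_state!r}")
    return joint_probs(history, bundle)[final_state]


def history_prob(history: Sequence[int], bundle: ModelBundle) -> float:
    """Marginal probability of observing ``history``."""
    f0, f1 = joint_probs(history, bundle)
    return f0 + f1


def posterior_abnormal(history: Sequence[int], bundle: ModelBundle) -> float:
    """P(abnormal at the last observation time | history), by Bayes' rule."""
    f0, f1 = joint_probs(history, bundle)
    total = f0 + f1
    if total == 0.0:
        raise ModelError(
            "history has zero probability under the model (degenerate emission probabilities)"
        )
    return f1 / total


def delta(history: Sequence[int], bundle: ModelBundle) -> float:
    """Δ statistic: expected per-step cost of not intervening minus intervening."""
    f0, f1 = joint_probs(history, bundle)
    K = bundle.costs.K
    return (1.0 - K) * f1 - K * f0


def _joint_arrays(n: int, bundle: ModelBundle) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward pass over all 2^n histories.

    Returns arrays ``(F0, F1)`` of shape ``(2**n,)`` indexed by the history
    integer (oldest bit = most significant).
    """
    if n < 1:
        raise ModelError(f"history length must be >= 1, got {n}")
    a0, a1 = stationary_distribution(bundle.system)
    det, sys_ = bundle.detector, bundle.system
    idx = np.arange(2 ** n)
    # bit i (1-based, oldest first) of each history
    bits = [(idx >> (n - 1 - i)) & 1 for i in range(n)]
    e0 = np.array([det.p00, det.p01])  # emission from normal, indexed by bit
    e1 = np.array([det.p10, det.p11])
    f0 = a0 * e0[bits[0]]
    f1 = a1 * e1[bits[0]]
    for b in bits[1:]:
        f0, f1 = (
            (f0 * sys_.q00 + f1 * sys_.q10) * e0[b],
            (f0 * sys_.q01 + f1 * sys_.q11) * e1[b],
        )
    return f0, f1


def delta_table(n: int, bundle: ModelBundle) -> np.ndarray:
    """Δ for every length-``n`` history, indexed like :class:`Strategy` tables."""
    f0, f1 = _joint_arrays(n, bundle)
    K = bundle.costs.K
    return (1.0 - K) * f1 - K * f0


def joint_table(n: int, bundle: ModelBundle) -> pd.DataFrame:
    """Joint probabilities of every length-``n`` history and final hidden state.

    Entries sum to 1 over the whole table.
    """
    f0, f1 = _joint_arrays(n, bundle)
    histories = [format(i, f"0{n}b") for i in range(2 ** n)]
    return pd.DataFrame({"history": histories, "joint_normal": f0, "joint_abnormal": f1})


def tabulate(n: int, bundle: ModelBundle) -> pd.DataFrame:
    """Per-history table of joints, marginal, posterior and Δ.

    Histories with zero probability get a NaN posterior (their Δ is exactly 0
    and they contribute to no loss).
    """
    df = joint_table(n, bundle)
    total = df["joint_normal"] + df["joint_abnormal"]
    K = bundle.costs.K
    with np.errstate(invalid="ignore", divide="ignore"):
        posterior = np.where(total > 0, df["joint_abnormal"] / total, np.nan)
    df["p_history"] = total
    df["posterior"] = posterior
    df["delta"] = (1.0 - K) * df["joint_abnormal"] - K * df["joint_normal"]
    return df
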