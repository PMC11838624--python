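"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities by explicit enumeration — exponential
in the history length — so they share no code path with the library's
forward-recursion implementations.
"""

from itertools import product

from survbit import ModelBundle, Strategy


def _params(bundle: ModelBundle):
    sys_, det = bundle.system, bundle.detector
    a1 = sys_.q01 / (sys_.q01 + sys_.q10)
    a = (1.0 - a1, a1)
    q = ((sys_.q00, sys_.q01), (sys_.q10, sys_.q11))
    p = ((det.p00, det.p01), (det.p10, det.p11))
    return a, q, p


def joint_brute(history, final_state, bundle: ModelBundle) -> float:
    """P(history, final hidden state) by summing over all 2^n hidden paths."""
    bits = tuple(history)
    a, q, p = _params(bundle)
    total = 0.0
    for path in product((0, 1), repeat=len(bits)):
        if path[-1] != final_state:
            continue
        pr = a[path[0]] * p[path[0]][bits[0]]
        for i in range(1, len(bits)):
            pr *= q[path[i - 1]][path[i]] * p[path[i]][bits[i]]
        total += pr
    return total


def delta_brute(history, bundle: ModelBundle) -> float:
    K = bundle.costs.K
    return ((1.0 - K) * joint_brute(history, 1, bundle)
            - K * joint_brute(history, 0, bundle))


def loss_brute(strategy: Strategy, bundle: ModelBundle) -> float:
    """Expected cost per step by enumerating every history of length n."""
    n = strategy.n
    a1 = bundle.system.q01 / (bundle.system.q01 + bundle.system.q10)
    K = bundle.costs.K
    s_n = bundle.costs.S[n]
    if n == 0:
        return (K if strategy.table[0] else a1) + s_n
    total = s_n
    for idx, bits in enumerate(product((0, 1), repeat=n)):
        j0 = joint_brute(bits, 0, bundle)
        j1 = joint_brute(bits, 1, bundle)
        if strategy.table[idx]:
            total += (j0 + j1) * K
        else:
            total += j1  # unmitigated abnormal step costs 1
    return total


def delta1_closed_form(i: int, bundle: ModelBundle) -> float:
    """One-bit closed form: (1-K) a1 p1i - K a0 p0i."""
    a, _, p = _params(bundle)
    K = bundle.costs.K
    return (1.0 - K) * a[1] * p[1][i] - K * a[0] * p[0][i]


def delta2_closed_form(i: int, j: int, bundle: ModelBundle) -> float:
    """Two-bit closed form over the four hidden-path terms."""
    a, q, p = _params(bundle)
    K = bundle.costs.K
    stay = a[1] * p[1][i] * q[1][1] * p[1][j] + a[0] * p[0][i] * q[0][1] * p[1][j]
    leave = a[1] * p[1][i] * q[1][0] * p[0][j] + a[0] * p[0][i] * q[0][0] * p[0][j]
    return (1.0 - K) * stay - K * leave
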