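"""Independent exact-arithmetic oracles used to verify the statistical core.

All probabilities are enumerated from integer binomial coefficients
(math.comb), sharing no code with the scipy-based implementation.
"""
from __future__ import annotations

from math import comb

# Two-sided tie gate: a table is at least as extreme as the observed one
# when its point probability does not exceed the observed one by more than
# one part in 1e7 (the conventional guard for floating-point ties, applied
# here in exact integer arithmetic).
_GATE_NUM = 10**7 + 1
_GATE_DEN = 10**7


def support(n1: int, n2: int, alt_total: int) -> range:
    """Feasible first-row alt counts given row sums n1, n2 and the alt
    column total."""
    return range(max(0, alt_total - n2), min(n1, alt_total) + 1)


def _numerator(n1: int, n2: int, alt_total: int, x: int) -> int:
    return comb(n1, x) * comb(n2, alt_total - x)


def fisher_right_tail_exact(a: int, b: int, c: int, d: int) -> float:
    """P(second-row alt >= d | margins), enumerated exactly."""
    n1, n2 = a + b, c + d
    alt_total = b + d
    denom = comb(n1 + n2, alt_total)
    num = sum(_numerator(n2, n1, alt_total, k)
              for k in support(n2, n1, alt_total) if k >= d)
    return num / denom


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: total probability of tables no more likely than
    the observed one (integer-arithmetic tie gate)."""
    n1, n2 = a + b, c + d
    alt_total = b + d
    denom = comb(n1 + n2, alt_total)
    obs = _numerator(n1, n2, alt_total, b)
    num = sum(w for k in support(n1, n2, alt_total)
              if (w := _numerator(n1, n2, alt_total, k)) * _GATE_DEN <= obs * _GATE_NUM)
    return num / denom


def right_tail_curve(n1: int, n2: int, alt_total: int) -> dict[int, float]:
    """Right-tail p over the whole support of the second-row alt count."""
    denom = comb(n1 + n2, alt_total)
    ks = list(support(n2, n1, alt_total))
    nums = [_numerator(n2, n1, alt_total, k) for k in ks]
    out = {}
    tail = sum(nums)
    for k, w in zip(ks, nums):
        out[k] = tail / denom
        tail -= w
    return out
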