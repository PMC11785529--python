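"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the Wasserstein
oracle integrates |U - V| over the piecewise-constant empirical CDFs
segment by segment, and the lag oracle evaluates the rule-of-thumb in
50-digit decimal arithmetic.
"""

from decimal import Decimal, getcontext

import numpy as np


def emd_bruteforce(u, v) -> float:
    """First Wasserstein distance by piecewise integration of |U - V|."""
    u = np.sort(np.asarray(u, dtype=float))
    v = np.sort(np.asarray(v, dtype=float))
    points = np.unique(np.concatenate([u, v]))
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        cdf_u = np.searchsorted(u, a, side="right") / u.size
        cdf_v = np.searchsorted(v, a, side="right") / v.size
        total += abs(cdf_u - cdf_v) * (b - a)
    return total


def newey_west_lag_decimal(T: int) -> int:
    """floor(4 * (T/100)^(2/9)) in 50-digit decimal arithmetic."""
    getcontext().prec = 50
    x = Decimal(T) / Decimal(100)
    val = 4 * (x.ln() * (Decimal(2) / Decimal(9))).exp()
    return int(val.to_integral_value(rounding="ROUND_FLOOR"))
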