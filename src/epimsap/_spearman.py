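"""Spearman rank correlation with an exact small-n permutation p-value.

scipy's t-approximation is poor for very short vectors, so for n <= 8
the two-sided p is computed by enumerating all n! permutations of one
ranking (average ranks for ties) and counting |rho| at least as extreme
as observed.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats

EXACT_N_MAX = 8


def spearman(x, y) -> tuple[float, float]:
    """Return (rho, two-sided p); exact enumeration when n <= 8.

    Raises ValueError on unequal lengths or n < 3; a constant input
    yields (nan, nan) — callers must flag it rather than interpret it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    rho = rho_of(rx, ry)
    if n > EXACT_N_MAX:
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p

    target = abs(rho) - 1e-12
    count = 0
    for perm in permutations(range(n)):
        if abs(rho_of(rx, ry[list(perm)])) >= target:
            count += 1
    return rho, count / factorial(n)
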