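"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the code paths they check: Fisher p-values come from
exact integer enumeration over all tables with fixed margins, BH q-values
from a literal reading of the step-up definition, and Welch p-values from the
closed-form two-sample formula.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def fisher_enumeration(a: int, b: int, c: int, d: int, two_sided: bool = True) -> float:
    """Exact Fisher p by enumerating every table with the observed margins.

    Point probabilities are exact integers over a common denominator, so the
    two-sided point-probability rule (include tables no more probable than
    the observed one) involves no floating-point tie ambiguity.
    """
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    denom = comb(n, c1)
    if denom == 0:
        return 1.0

    def weight(k: int) -> int:
        return comb(r1, k) * comb(r2, c1 - k)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = weight(a)
    if two_sided:
        total = sum(weight(k) for k in range(lo, hi + 1) if weight(k) <= obs)
    else:  # enrichment: P(X >= a)
        total = sum(weight(k) for k in range(a, hi + 1))
    return total / denom


def bh_stepup(pvalues) -> np.ndarray:
    """Literal step-up definition: q(i) = min over j with rank >= rank(i) of
    m * p(j) / rank(j), clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[order[pos]] = min(1.0, min(candidates))
    return q


def welch_p(x, y) -> float:
    """Closed-form two-sided Welch t-test with Welch–Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2 * stats.t.sf(abs(t), df))
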