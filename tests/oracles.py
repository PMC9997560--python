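"""Brute-force statistical oracles, independent of the package internals."""

from __future__ import annotations

import math

import numpy as np


def chi2_2xk_oracle(a, b) -> float:
    """Pearson statistic on the 2xk table, computed as literal sum (O-E)^2/E."""
    table = np.array([a, b], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def chi2_gof_oracle(observed, weights) -> float:
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(weights, dtype=float)
    expected = obs.sum() * w / w.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums P(x) over all tables with the observed margins whose probability
    is no greater than the observed table's (minimum-likelihood rule).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )
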