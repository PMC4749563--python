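"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: tetrad classes by
exhaustive chromatid enumeration, Fisher p-values by hypergeometric
enumeration over the fixed margins, smoothing by direct convolution,
fold changes by direct summation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tetrad_class_probs_bruteforce(k: int) -> tuple[float, float, float]:
    """(P(PD), P(TT), P(NPD)) after k crossovers by enumerating all 4^k
    non-sister chromatid-pair assignments."""
    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
    counts = {"PD": 0, "TT": 0, "NPD": 0}
    for combo in itertools.product(pairs, repeat=k):
        distal = [0, 0, 1, 1]
        for i, j in combo:
            distal[i], distal[j] = distal[j], distal[i]
        r = (distal[0] != 0) + (distal[1] != 0) + (distal[2] != 1) + (distal[3] != 1)
        counts["PD" if r == 0 else ("TT" if r == 2 else "NPD")] += 1
    total = 4**k
    return counts["PD"] / total, counts["TT"] / total, counts["NPD"] / total


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p-value by exhaustive enumeration over the margins.

    Sums hypergeometric probabilities of all tables at least as extreme
    (probability <= observed, with the standard 1+1e-7 tie tolerance).
    """
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeometric(n, col1, row1)
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def hann_direct(values: np.ndarray, window: int) -> np.ndarray:
    """Direct (non-FFT, loop) truncated-and-renormalized Hann smoothing."""
    j = np.arange(window, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * j / (window - 1)))
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        kern = w[lo - (i - half) : hi - (i - half)]
        out[i] = float((values[lo:hi] * kern).sum() / kern.sum())
    return out


def segment_density_direct(values: np.ndarray, start: int, end: int) -> float:
    """Signal per kb in [start, end), direct summation."""
    start = max(start, 0)
    end = min(end, len(values))
    return float(values[start:end].sum()) / ((end - start) / 1000.0) if end > start else float("nan")
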