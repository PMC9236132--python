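"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately naive O(n^2) pure-Python implementations,
kept separate from the package's vectorized code paths so they can serve
as independent references.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ------------------------------------------------------------- entropy oracles

def apen_oracle(x, m, r):
    """Direct template counting, self-matches included, Chebyshev distance."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        T = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in T:
            c = 0
            for tj in T:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    c += 1
            total += math.log(c / len(T))
        return total / len(T)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    """Pairwise match counting over the first n-m templates, no self-matches."""
    x = list(map(float, x))
    n = len(x)
    Tm = [x[i:i + m] for i in range(n - m)]
    Tm1 = [x[i:i + m + 1] for i in range(n - m)]
    B = A = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(a - b) for a, b in zip(Tm[i], Tm[j])) <= r:
                B += 1
            if max(abs(a - b) for a, b in zip(Tm1[i], Tm1[j])) <= r:
                A += 1
    if A == 0 or B == 0:
        return None
    return -math.log(A / B)


def pen_oracle(x, D):
    """Ordinal-pattern frequencies with order-of-appearance tie-breaks."""
    x = list(map(float, x))
    pats = Counter()
    for i in range(len(x) - D + 1):
        win = x[i:i + D]
        pattern = tuple(sorted(range(D), key=lambda k: (win[k], k)))
        pats[pattern] += 1
    total = sum(pats.values())
    return -sum((c / total) * math.log2(c / total) for c in pats.values())


def sscen_oracle(x, D, K):
    """Histogram entropy of pairwise window dot products, coded by hand."""
    x = [float(v) for v in x]
    mean = sum(x) / len(x)
    x = [v - mean for v in x]
    wins = [x[i:i + D] for i in range(len(x) - D + 1)]
    dots = []
    for i in range(len(wins)):
        for j in range(i + 1, len(wins)):
            dots.append(sum(a * b for a, b in zip(wins[i], wins[j])))
    lo, hi = min(dots), max(dots)
    if hi == lo or K == 1:
        return 0.0
    edges = [lo + k * (hi - lo) / K for k in range(K + 1)]
    counts = [0] * K
    for v in dots:
        for k in range(K):
            # last bin is closed above at the true maximum (rounded edge
            # arithmetic can place lo + K*(hi-lo)/K a hair below hi)
            upper_ok = v <= hi if k == K - 1 else v < edges[k + 1]
            if edges[k] <= v and upper_ok:
                counts[k] += 1
                break
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)
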