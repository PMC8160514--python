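"""Independent oracles used by the test suite.

Everything here is deliberately naive: exact rational arithmetic and
double loops, sharing no code with the package paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def exact_hypergeom_tail(c: int, M: int, K: int, n: int) -> Fraction:
    """P(X >= c) for X ~ Hypergeom(M, K, n), by exact enumeration."""
    lo = max(0, n - (M - K))
    hi = min(n, K)
    num = sum(comb(K, k) * comb(M - K, n - k) for k in range(max(c, lo), hi + 1))
    return Fraction(num, comb(M, n))


def exact_fisher_greater(c: int, d: int, a: int, b: int) -> Fraction:
    """One-sided Fisher exact p for [[c, d], [a, b]], alternative: the top
    row enriched for the first column.  Conditions on all margins."""
    return exact_hypergeom_tail(c, a + b + c + d, a + c, c + d)


def exact_binom_tail(k: int, n: int, p0: Fraction = Fraction(1, 2)) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p0), term-by-term exact summation."""
    p0 = Fraction(p0)
    return sum(
        comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
    ) if k <= n else Fraction(0)


def brute_force_stable_pairs(values: np.ndarray, genes: list[str], threshold: float):
    """Double loop over all unordered gene pairs and samples.

    Returns {(greater, lesser): support} using count >= ceil(threshold*n)
    with exact integer comparison (count * denominator >= numerator trick
    avoided by rational comparison).
    """
    import math

    n = values.shape[1]
    need = math.ceil(threshold * n - 1e-9)
    pairs = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gt = int((values[i] > values[j]).sum())
            lt = int((values[i] < values[j]).sum())
            if gt >= need:
                pairs[(genes[i], genes[j])] = gt / n
            elif lt >= need:
                pairs[(genes[j], genes[i])] = lt / n
    return pairs


def brute_force_auc(scores, labels) -> float:
    """All-pairs comparison count: wins + half-ties over pos x neg pairs."""
    scores = list(scores)
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def monotone_transforms(rng: np.random.Generator):
    """Strictly increasing per-sample transforms for invariance checks."""
    slope = float(rng.uniform(0.5, 3.0))
    offset = float(rng.uniform(0.0, 10.0))
    return [
        ("log1p", np.log1p),
        ("rank", lambda col: np.argsort(np.argsort(col)).astype(float)),
        ("affine", lambda col, s=slope, o=offset: s * col + o),
    ]
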