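"""Deliberately naive reference implementations used as independent oracles.

Everything here is O(n^2)-style explicit summation, kept separate from (and
never importing) the package's own numerics.
"""

import math

import numpy as np


def naive_rank(v):
    """Average ranks with ties, by counting."""
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        out[i] = less + (equal + 1) / 2.0
    return out


def naive_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt(np.sum(xm**2)) * np.sqrt(np.sum(ym**2))
    if denom == 0:
        return np.nan
    return float(np.sum(xm * ym) / denom)


def naive_spearman(x, y):
    return naive_pearson(naive_rank(x), naive_rank(y))


def naive_kendall(x, y):
    """Tau-b by explicit pair enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    denom = np.sqrt((concordant + discordant + tx) * (concordant + discordant + ty))
    if denom == 0:
        return np.nan
    return float((concordant - discordant) / denom)


def naive_cosine(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    denom = np.sqrt(np.sum(x**2)) * np.sqrt(np.sum(y**2))
    if denom == 0:
        return np.nan
    return float(np.sum(x * y) / denom)


NAIVE_CORRELATIONS = {
    "spearman": naive_spearman,
    "pearson": naive_pearson,
    "kendall": naive_kendall,
    "cosine": naive_cosine,
}


def exact_hypergeom_tail(M, a, b, k):
    """Upper-tail P(X >= k) by explicit combinatorial summation."""
    total = 0
    for i in range(k, min(a, b) + 1):
        total += math.comb(b, i) * math.comb(M - b, a - i)
    return total / math.comb(M, a)
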