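"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over matrix cells, deliberately
ignorant of the vectorized implementations it checks.
"""

from collections import Counter

import numpy as np


def naive_recurrence_matrix(y, radius):
    n = len(y)
    R = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            if abs(y[i] - y[j]) <= radius:
                R[i, j] = 1
    return R


def naive_rr(R):
    n = R.shape[0]
    total = 0
    for i in range(n):
        for j in range(n):
            total += int(R[i, j])
    return 100.0 * total / (n * n)


def _runs(bits):
    out, run = [], 0
    for b in bits:
        if b:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def naive_diagonal_hist(R):
    n = R.shape[0]
    counts = Counter()
    for k in range(1, n):
        for offset in (k, -k):
            d = [R[i, i + offset] for i in range(n) if 0 <= i + offset < n]
            counts.update(_runs(d))
    return dict(counts)


def naive_vertical_hist(R):
    """Vertical runs per column with the main-diagonal cell deleted."""
    n = R.shape[0]
    counts = Counter()
    for j in range(n):
        col = [R[i, j] for i in range(n) if i != j]
        counts.update(_runs(col))
    return dict(counts)


def naive_det(R, l_min=2):
    hist = naive_diagonal_hist(R)
    denom = sum(l * c for l, c in hist.items())
    if denom == 0:
        return 0.0
    return 100.0 * sum(l * c for l, c in hist.items() if l >= l_min) / denom


def naive_lam(R, v_min=2):
    hist = naive_vertical_hist(R)
    denom = sum(l * c for l, c in hist.items())
    if denom == 0:
        return 0.0
    return 100.0 * sum(l * c for l, c in hist.items() if l >= v_min) / denom


def naive_exhaustive_entropy(R, q=2):
    """Plug-in entropy over every q x q block, counted cell by cell."""
    n = R.shape[0]
    counts = Counter()
    for i in range(n - q + 1):
        for j in range(n - q + 1):
            key = tuple(int(R[i + di, j + dj]) for dj in range(q) for di in range(q))
            counts[key] += 1
    total = sum(counts.values())
    ent = 0.0
    for c in counts.values():
        p = c / total
        ent -= p * np.log(p)
    return ent


def random_symmetric_binary(n, rng):
    """Random symmetric 0/1 matrix with unit diagonal."""
    A = rng.integers(0, 2, size=(n, n)).astype(np.uint8)
    R = np.triu(A, 1)
    R = R + R.T
    np.fill_diagonal(R, 1)
    return R
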