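"""Independent brute-force reference implementations used only by tests.

Each oracle follows the textbook definition as directly as possible
(explicit loops, no shared code with the package) so that agreement with
the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def relief_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-class Relief, full deterministic pass, range-normalized diffs,
    Manhattan neighbor distance, ties to the lowest index."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, a = X.shape
    lo, hi = X.min(0), X.max(0)
    rng = hi - lo

    def d(j, u, v):
        if rng[j] == 0:
            return 0.0
        return abs(X[u, j] - X[v, j]) / rng[j]

    def dist(u, v):
        return sum(d(j, u, v) for j in range(a))

    w = np.zeros(a)
    for i in range(n):
        hits = [u for u in range(n) if u != i and y[u] == y[i]]
        misses = [u for u in range(n) if y[u] != y[i]]
        nh = min(hits, key=lambda u: (dist(i, u), u))
        nm = min(misses, key=lambda u: (dist(i, u), u))
        for j in range(a):
            w[j] += -d(j, i, nh) / n + d(j, i, nm) / n
    return w


def relieff_oracle(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Multi-class ReliefF, full deterministic pass: k nearest hits, k
    nearest misses per other class weighted by p(C)/(1 - p(class(i)))."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, a = X.shape
    lo, hi = X.min(0), X.max(0)
    rng = hi - lo
    classes = sorted(set(y.tolist()))
    prior = {c: float(np.mean(y == c)) for c in classes}

    def d(j, u, v):
        if rng[j] == 0:
            return 0.0
        return abs(X[u, j] - X[v, j]) / rng[j]

    def dist(u, v):
        return sum(d(j, u, v) for j in range(a))

    def knn(i, candidates):
        return sorted(candidates, key=lambda u: (dist(i, u), u))[:k]

    w = np.zeros(a)
    for i in range(n):
        hits = knn(i, [u for u in range(n) if u != i and y[u] == y[i]])
        for j in range(a):
            w[j] -= sum(d(j, i, h) for h in hits) / (n * k)
        for c in classes:
            if c == y[i]:
                continue
            misses = knn(i, [u for u in range(n) if y[u] == c])
            scale = prior[c] / (1.0 - prior[y[i]])
            for j in range(a):
                w[j] += scale * sum(d(j, i, u) for u in misses) / (n * k)
    return w


def sample_entropy_oracle(x: np.ndarray, m: int, r: float) -> float:
    """O(n^2) template counting straight from the definition; the same
    n - m template start points at both lengths, self-matches excluded."""
    x = np.asarray(x, float)
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
                if max(abs(x[i + t] - x[j + t]) for t in range(m + 1)) <= r:
                    a += 1
    if b == 0:
        return 0.0
    if a == 0:
        return -np.log(1.0 / (b + 1))
    return -np.log(a / b)
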