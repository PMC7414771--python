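"""Shared fixtures and independent brute-force oracles.

The oracles implement the printed measure definitions with literal loops
(triple loops, Bellman-Ford relaxation, exhaustive set-partition search) so
they share no code path with the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.5):
    """Random symmetric weight matrix, zero diagonal, weights in (0, 1]."""
    mask = rng.random((n, n)) < density
    w = rng.uniform(0.05, 1.0, (n, n)) * mask
    w = np.triu(w, 1)
    w = w + w.T
    if w.sum() == 0:  # guarantee at least one edge
        w[0, 1] = w[1, 0] = 0.5
    return w


def bf_distances(w: np.ndarray) -> np.ndarray:
    """Bellman-Ford-style relaxation with edge lengths 1/w (independent of
    the package's Floyd-Warshall / Dijkstra)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for _ in range(n):
        changed = False
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if d[i, k] + d[k, j] < d[i, j] - 1e-15:
                        d[i, j] = d[i, k] + d[k, j]
                        changed = True
        if not changed:
            break
    return d


def bf_clustering(w: np.ndarray) -> np.ndarray:
    """Barrat weighted clustering by literal triple loop over ordered pairs."""
    n = w.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nn = [j for j in range(n) if w[i, j] > 0]
        k = len(nn)
        if k < 2:
            continue
        s = sum(w[i, j] for j in nn)
        total = 0.0
        for j in nn:
            for h in nn:
                if j == h:
                    continue
                if w[j, h] > 0:
                    total += (w[i, j] + w[i, h]) / 2.0
        c[i] = total / (s * (k - 1))
    return c


def bf_local_efficiency(w: np.ndarray) -> np.ndarray:
    """Local efficiency with full-network distances, literal loops."""
    n = w.shape[0]
    d = bf_distances(w)
    e = np.zeros(n)
    for i in range(n):
        nn = [j for j in range(n) if w[i, j] > 0]
        k = len(nn)
        if k < 2:
            continue
        total = 0.0
        for j in nn:
            for h in nn:
                if j == h:
                    continue
                if np.isfinite(d[j, h]) and d[j, h] > 0:
                    total += 1.0 / d[j, h]
        e[i] = total / (k * (k - 1))
    return e


def bf_modularity(w: np.ndarray, labels) -> float:
    """Q by literal double loop over ordered node pairs."""
    labels = list(labels)
    two_w = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - s[i] * s[j] / two_w
    return q / two_w


def set_partitions(n: int):
    """All set partitions of range(n) as label lists (restricted growth)."""
    if n == 1:
        yield [0]
        return
    for p in set_partitions(n - 1):
        m = max(p)
        for lab in range(m + 2):
            yield p + [lab]


def exhaustive_max_q(w: np.ndarray) -> float:
    best = -np.inf
    for p in set_partitions(w.shape[0]):
        q = bf_modularity(w, p)
        if q > best:
            best = q
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
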