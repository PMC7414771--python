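"""Numba kernel for simulated-annealing modularity maximization.

The move set is single-node reassignment (including to an empty module,
which creates one) plus occasional module merges and random bipartition
splits.  Q is tracked incrementally; the best partition encountered is
returned.  All randomness comes from the seeded kernel RNG, so a run is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sa_kernel(
    w: np.ndarray,
    seed: int,
    t0: float,
    cooling: float,
    tmin: float,
    moves_per_temp: int,
    p_single: float,
):  # pragma: no cover - exercised through maximize_modularity_sa
    np.random.seed(seed)
    n = w.shape[0]
    s = np.zeros(n)
    for i in range(n):
        for j in range(n):
            s[i] += w[i, j]
    two_w = s.sum()
    inv2w = 1.0 / two_w

    labels = np.arange(n)
    size = np.ones(n, np.int64)
    modstr = s.copy()  # S[m]: total strength of module m
    # M[i, m]: total weight from node i into module m
    m_node = w.copy()

    # Q of the singleton partition: only diagonal delta terms, w_ii = 0
    q = 0.0
    for i in range(n):
        q -= (s[i] * inv2w) ** 2

    best_q = q
    best_labels = labels.copy()

    t = t0
    while t > tmin:
        for _ in range(moves_per_temp):
            u = np.random.random()
            if u < p_single:
                i = np.random.randint(0, n)
                a = labels[i]
                b = np.random.randint(0, n)
                if b == a:
                    continue
                dq = 2.0 * (m_node[i, b] - m_node[i, a]) * inv2w - 2.0 * s[i] * (
                    modstr[b] - modstr[a] + s[i]
                ) * inv2w * inv2w
                if dq > 0.0 or np.random.random() < np.exp(dq / t):
                    labels[i] = b
                    size[a] -= 1
                    size[b] += 1
                    modstr[a] -= s[i]
                    modstr[b] += s[i]
                    for j in range(n):
                        m_node[j, a] -= w[i, j]
                        m_node[j, b] += w[i, j]
                    q += dq
            elif u < p_single + (1.0 - p_single) * 0.5:
                # merge two distinct non-empty modules
                a = labels[np.random.randint(0, n)]
                b = labels[np.random.randint(0, n)]
                if a == b:
                    continue
                cross = 0.0
                for i in range(n):
                    if labels[i] == a:
                        cross += m_node[i, b]
                dq = 2.0 * cross * inv2w - 2.0 * modstr[a] * modstr[b] * inv2w * inv2w
                if dq > 0.0 or np.random.random() < np.exp(dq / t):
                    for i in range(n):
                        if labels[i] == b:
                            labels[i] = a
                    size[a] += size[b]
                    size[b] = 0
                    modstr[a] += modstr[b]
                    modstr[b] = 0.0
                    for j in range(n):
                        m_node[j, a] += m_node[j, b]
                        m_node[j, b] = 0.0
                    q += dq
            else:
                # split a module by a random bipartition
                a = labels[np.random.randint(0, n)]
                if size[a] < 2:
                    continue
                c = -1
                for m in range(n):
                    if size[m] == 0:
                        c = m
                        break
                if c < 0:
                    continue
                side = np.zeros(n, np.uint8)
                moved = 0
                members = 0
                for i in range(n):
                    if labels[i] == a:
                        members += 1
                        if np.random.random() < 0.5:
                            side[i] = 1
                            moved += 1
                if moved == 0 or moved == members:
                    continue
                cross = 0.0
                s_moved = 0.0
                for i in range(n):
                    if labels[i] == a and side[i] == 1:
                        s_moved += s[i]
                        for j in range(n):
                            if labels[j] == a and side[j] == 0:
                                cross += w[i, j]
                s_stay = modstr[a] - s_moved
                dq = -2.0 * cross * inv2w + 2.0 * s_moved * s_stay * inv2w * inv2w
                if dq > 0.0 or np.random.random() < np.exp(dq / t):
                    for i in range(n):
                        if labels[i] == a and side[i] == 1:
                            labels[i] = c
                            for j in range(n):
                                m_node[j, a] -= w[i, j]
                                m_node[j, c] += w[i, j]
                    size[a] -= moved
                    size[c] = moved
                    modstr[a] = s_stay
                    modstr[c] = s_moved
                    q += dq
            if q > best_q:
                best_q = q
                best_labels = labels.copy()
        t *= cooling
    return best_labels, best_q
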