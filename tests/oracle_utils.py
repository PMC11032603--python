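"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def dp_edit_distance(a: str, b: str) -> int:
    """Full Wagner-Fischer dynamic-programming table."""
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
    return d[la][lb]


def loop_contact_map(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Three-nested-loop scalar evaluation of the diff/mul fusion."""
    m, d1 = t1.shape
    n, _ = t2.shape
    out = np.empty((2 * d1, m, n))
    for k in range(d1):
        for i in range(m):
            for j in range(n):
                out[k, i, j] = abs(t1[i, k] - t2[j, k])
                out[d1 + k, i, j] = t1[i, k] * t2[j, k]
    return out


def scalar_pair_probability(pm: np.ndarray, gamma: float, eta: float, p0: float) -> float:
    """Scalar-loop evaluation of the global pooling head."""
    m, n = pm.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += pm[i, j]
    mean = total / (m * n)
    var = 0.0
    for i in range(m):
        for j in range(n):
            var += (pm[i, j] - mean) ** 2
    var /= m * n
    q_sum = 0.0
    q_count = 0
    for i in range(m):
        for j in range(n):
            q = pm[i, j] - mean - gamma * var
            if q > 0:
                q_sum += q
                q_count += 1
    p_q = q_sum / (q_count + 1)
    return 1.0 / (1.0 + np.exp(-eta * (p_q - p0)))


def brute_force_scan(arranged: str, seed: str, max_distance: int) -> list[tuple[int, int]]:
    """Edit distance of every 13-mer window via the DP table."""
    hits = []
    k = len(seed)
    for i in range(len(arranged) - k + 1):
        d = dp_edit_distance(arranged[i:i + k], seed)
        if d <= max_distance:
            hits.append((i, d))
    return hits


def all_sequences(max_len: int, alphabet: str = "AGCU") -> list[str]:
    """Every sequence over *alphabet* with length 0..max_len."""
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + b for s in frontier for b in alphabet]
        out.extend(frontier)
    return out
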