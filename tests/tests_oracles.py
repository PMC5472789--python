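"""Shared brute-force oracles, independent of the library implementations."""

import numpy as np


def brute_force_dtw(a, b):
    """Exhaustive enumeration of all monotone warping paths."""
    a = np.atleast_2d(np.asarray(a, float).reshape(len(a), -1))
    b = np.atleast_2d(np.asarray(b, float).reshape(len(b), -1))
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += np.linalg.norm(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]
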