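"""Independent brute-force oracles used to verify the library's algorithms.

These deliberately avoid the library's own code paths: path enumeration is
recursive, statistics are per-pixel Python loops.
"""

from __future__ import annotations

import numpy as np


def enumerate_min_path(
    g: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    w_min: float,
    max_step: int,
) -> tuple[list[int], float]:
    """Exhaustively enumerate all column-monotone paths and pick the best.

    Same contract as the shortest-path solver: one row per column inside
    [lo[x], hi[x]), |step| <= max_step, free endpoints, cost = sum of
    2 - (g_a + g_b) + w_min over edges; ties broken by smallest row sum,
    then lexicographically smallest path.
    """
    n_rows, n_cols = g.shape
    best: tuple[float, int, tuple[int, ...]] | None = None

    def extend(path: list[int], cost: float) -> None:
        nonlocal best
        x = len(path)
        if x == n_cols:
            key = (cost, sum(path), tuple(path))
            if best is None or key < best:
                best = key
            return
        for r in range(lo[x], hi[x]):
            if path and abs(r - path[-1]) > max_step:
                continue
            c = cost
            if path:
                c += 2.0 - (g[path[-1], x - 1] + g[r, x]) + w_min
            extend(path + [r], c)

    extend([], 0.0)
    if best is None:
        return None, None  # infeasible instance
    return list(best[2]), best[0]


def brute_force_band_mean(vol, up_rows, lo_rows):
    """Per-pixel vertical averaging by explicit loops."""
    n_b, n_d, n_a = vol.shape
    out = np.zeros((n_b, n_a))
    for y in range(n_b):
        for x in range(n_a):
            a = int(round(up_rows[y, x]))
            b = int(round(lo_rows[y, x]))
            if b > a:
                out[y, x] = vol[y, a:b, x].mean()
            else:
                out[y, x] = vol[y, a, x]
    return out
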