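"""Independent reference implementations used to cross-check the package.

These are deliberately written with plain loops / exhaustive enumeration,
not with the library calls the implementation uses.
"""

import math

import numpy as np


def brute_force_decide(grid, cfg):
    """Exhaustive BFS component enumeration + cascade rules."""
    h, w = grid.shape
    surviving = {
        (i, j)
        for i in range(h)
        for j in range(w)
        if np.isfinite(grid[i, j]) and grid[i, j] >= cfg.window_threshold
    }
    if cfg.connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    retained = []
    for start in sorted(surviving):
        if start in seen:
            continue
        stack, comp = [start], set()
        seen.add(start)
        while stack:
            cell = stack.pop()
            comp.add(cell)
            for di, dj in nbrs:
                nxt = (cell[0] + di, cell[1] + dj)
                if nxt in surviving and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if len(comp) < cfg.min_component_windows:
            continue
        mean_p = math.fsum(grid[c] for c in comp) / len(comp)
        if mean_p >= cfg.mean_prob_threshold:
            retained.append((frozenset(comp), mean_p))
    return retained


def brute_force_radial_average(power2d, fu, fv, df, max_freq):
    """Double-loop radial binning (nearest bin center, DC bin excluded)."""
    n_bins = int(np.floor(max_freq / df + 0.5))
    sums = np.zeros(n_bins + 1)
    counts = np.zeros(n_bins + 1)
    for i in range(len(fu)):
        for j in range(len(fv)):
            r = math.hypot(fu[i], fv[j])
            k = int(np.floor(r / df + 0.5))
            if 1 <= k <= n_bins:
                sums[k] += power2d[i, j]
                counts[k] += 1
    vals = np.full(n_bins, np.nan)
    good = counts[1:] > 0
    vals[good] = sums[1:][good] / counts[1:][good]
    return vals
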