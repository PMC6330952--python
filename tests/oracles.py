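"""Independent brute-force oracles used to check the fast implementations.

Each oracle is written from the operation's definition, deliberately using
a different algorithmic strategy (full-grid scans, exhaustive enumeration)
than the implementation it verifies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def window_max_seeds(values: np.ndarray, keep: np.ndarray, window: int):
    """Exhaustive per-pixel moving-window maximum scan.

    Returns the set of (row, col) positions that are unmasked and equal
    the maximum over unmasked pixels of the clipped window centered there.
    """
    half = window // 2
    nrows, ncols = values.shape
    seeds = set()
    for r in range(nrows):
        for c in range(ncols):
            if not keep[r, c]:
                continue
            best = -math.inf
            for rr in range(max(0, r - half), min(nrows, r + half + 1)):
                for cc in range(max(0, c - half), min(ncols, c + half + 1)):
                    if keep[rr, cc] and values[rr, cc] > best:
                        best = values[rr, cc]
            if values[r, c] == best:
                seeds.add((r, c))
    return seeds


def bfs_grow(values, seeds, keep, perc_thresh, dist_max):
    """Level-synchronous region growing by repeated full-grid sweeps.

    ``seeds`` is a list of (seed_id, row, col, value). Every sweep scans
    every unlabeled unmasked pixel for labeled 4-neighbors whose region's
    two conditions (strict distance to seed, strict value threshold) it
    satisfies, and assigns all accepted pixels simultaneously at the end
    of the sweep — contested pixels to the nearest seed, ties to the
    lower seed id.
    """
    nrows, ncols = values.shape
    labels = np.zeros((nrows, ncols), dtype=int)
    pos = {}
    val = {}
    for sid, r, c, v in seeds:
        labels[r, c] = sid
        pos[sid] = (r, c)
        val[sid] = v
    while True:
        additions = {}
        for r in range(nrows):
            for c in range(ncols):
                if labels[r, c] != 0 or not keep[r, c]:
                    continue
                candidates = []
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] > 0:
                        n = labels[rr, cc]
                        sr, sc = pos[n]
                        dist = math.hypot(r - sr, c - sc)
                        if dist < dist_max and values[r, c] > val[n] * perc_thresh:
                            candidates.append((dist, n))
                if candidates:
                    additions[(r, c)] = min(candidates)
        if not additions:
            break
        for (r, c), (_, n) in additions.items():
            labels[r, c] = n
    return labels


def greedy_one_to_one(distance: np.ndarray):
    """Exhaustive greedy matching over every entry of a distance table.

    Pairs are accepted in ascending distance (ties by row then column
    index), each row and column used at most once.
    """
    order = sorted(
        (distance[i, j], i, j)
        for i in range(distance.shape[0])
        for j in range(distance.shape[1])
    )
    used_rows, used_cols, pairs = set(), set(), []
    for _, i, j in order:
        if i not in used_rows and j not in used_cols:
            used_rows.add(i)
            used_cols.add(j)
            pairs.append((i, j))
    return pairs


def best_subset(score_fn, n_bands: int, size: int):
    """Exhaustive search of the best band subset of a given size."""
    best_val, best_sub = -math.inf, None
    for sub in itertools.combinations(range(n_bands), size):
        v = score_fn(list(sub))
        if v > best_val:
            best_val, best_sub = v, set(sub)
    return best_sub, best_val


def hull_area(points) -> float:
    """Convex hull area via scipy's qhull (independent of shapely)."""
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except Exception:
        return 0.0  # degenerate (collinear)
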