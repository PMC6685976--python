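"""Independent brute-force reference implementations used by the tests.

These deliberately use plain Python loops and a direct reading of the
definitions, so they share no code path with the package internals they
check.
"""

from __future__ import annotations

import math

import numpy as np

BALL_EPS = 1e-9


def brute_density_delta(volume: np.ndarray, radii):
    """O(n^2) rho/delta/nearest-higher by direct enumeration.

    Order convention matches the package: voxel j is "denser" than i iff
    it precedes i in (rho desc, t, y, x) order; the first voxel overall
    gets delta = max pairwise distance (delta = 1 for a singleton).
    """
    voxels = [tuple(v) for v in np.argwhere(np.asarray(volume, bool))]
    n = len(voxels)
    r = np.asarray(radii, dtype=float)
    scaled = [np.asarray(v, float) / r for v in voxels]

    def dist(i, j):
        return math.sqrt(float(((scaled[i] - scaled[j]) ** 2).sum()))

    rho = []
    for i in range(n):
        count = 0
        for j in range(n):
            if dist(i, j) <= 1.0 + BALL_EPS:
                count += 1
        rho.append(count)

    order = sorted(range(n), key=lambda i: (-rho[i],) + voxels[i])
    rank = {i: k for k, i in enumerate(order)}

    delta = [0.0] * n
    nearest = [-1] * n
    for i in range(n):
        higher = [j for j in range(n) if rank[j] < rank[i]]
        if not higher:
            if n == 1:
                delta[i] = 1.0
            else:
                # densest voxel: max distance over all pairs of voxels
                delta[i] = max(
                    dist(a, b) for a in range(n) for b in range(a + 1, n)
                )
        else:
            best = min(dist(i, j) for j in higher)
            cands = [j for j in higher if dist(i, j) == best]
            nearest[i] = min(cands, key=lambda j: rank[j])
            delta[i] = best
    return voxels, rho, delta, nearest


def brute_assign(voxels, rho, nearest, centers):
    """Recursive chain-following cluster assignment (memoized)."""
    center_label = {c: k for k, c in enumerate(centers)}
    memo = {}

    def label_of(i):
        if i in memo:
            return memo[i]
        if i in center_label:
            memo[i] = center_label[i]
        elif nearest[i] < 0:
            memo[i] = -1
        else:
            memo[i] = label_of(nearest[i])
        return memo[i]

    return [label_of(i) for i in range(len(voxels))]


def brute_min_distance_to_mask(point_xy, mask, pixel_size=1.0):
    """Min Euclidean distance from (x, y) to the mask, in um.

    Region membership is pixelwise: a point whose containing pixel is
    true is at distance 0; otherwise the minimum distance to any true
    pixel center.
    """
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    x, y = point_xy
    if mask[int(round(y)), int(round(x))]:
        return 0.0
    d = np.sqrt((xs - x) ** 2 + (ys - y) ** 2)
    return float(d.min()) * pixel_size


def brute_ks_statistic(a, b):
    """sup |ECDF_a - ECDF_b| by sweeping all sample points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    pts = np.concatenate([a, b])
    stat = 0.0
    for p in pts:
        fa = np.sum(a <= p) / len(a)
        fb = np.sum(b <= p) / len(b)
        stat = max(stat, abs(fa - fb))
    return stat


def brute_optimal_matching(prev, cur, max_dist):
    """Exhaustive min-total-distance matching between two frames' points.

    Used as linking oracle for well-separated particles where greedy and
    optimal matching must coincide.
    """
    import itertools

    prev = list(prev)
    cur = list(cur)
    best = None
    best_cost = np.inf
    k = min(len(prev), len(cur))
    for m in range(k, -1, -1):
        for pi in itertools.permutations(range(len(prev)), m):
            for ci in itertools.combinations(range(len(cur)), m):
                pairs = list(zip(pi, ci))
                ds = [
                    math.hypot(prev[i][0] - cur[j][0], prev[i][1] - cur[j][1])
                    for i, j in pairs
                ]
                if any(d > max_dist for d in ds):
                    continue
                cost = sum(ds)
                if len(pairs) > (0 if best is None else len(best)) or (
                    best is not None and len(pairs) == len(best) and cost < best_cost
                ):
                    best, best_cost = pairs, cost
        if best is not None and len(best) == m:
            break
    return best or []
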