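"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from thermotrack.core import Track

DT = 1.0 / 15.0


def make_track(positions, dt: float = DT, track_id: int = 0,
               gap_flags=None) -> Track:
    """Track from an (N, 2) position array at a uniform frame interval."""
    positions = np.asarray(positions, dtype=float)
    t = np.arange(len(positions)) * dt
    return Track(track_id=track_id, t=t, x=positions[:, 0], y=positions[:, 1],
                 gap_flags=gap_flags)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# --------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)
# --------------------------------------------------------------------------

def naive_dbscan(points: np.ndarray, eps: float, min_samples: int):
    """Reachability-closure DBSCAN: returns a list of frozensets of point
    indices (clusters); noise points appear in no cluster."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_samples}
    clusters = []
    unvisited_core = set(core)
    while unvisited_core:
        seed = unvisited_core.pop()
        cluster = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in neighbors[i]:
                if j in core and j not in cluster:
                    cluster.add(j)
                    frontier.append(j)
                    unvisited_core.discard(j)
                elif j not in cluster:
                    cluster.add(j)  # border point
        clusters.append(frozenset(cluster))
    return clusters


def brute_force_matching_cost(src: np.ndarray, dst: np.ndarray,
                              max_dist: float) -> float:
    """Minimum over all partial injective matchings of
    sum(d_ij^2) + max_dist^2 * (#unmatched sources + #unmatched targets),
    with links allowed only when d_ij <= max_dist. Exponential enumeration."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    n, m = len(src), len(dst)
    b = max_dist ** 2
    best = b * (n + m)  # match nothing
    indices = list(range(m))
    for k in range(1, min(n, m) + 1):
        for src_subset in itertools.combinations(range(n), k):
            for dst_perm in itertools.permutations(indices, k):
                cost = 0.0
                feasible = True
                for i, j in zip(src_subset, dst_perm):
                    d = np.linalg.norm(src[i] - dst[j])
                    if d > max_dist:
                        feasible = False
                        break
                    cost += d ** 2
                if not feasible:
                    continue
                cost += b * ((n - k) + (m - k))
                best = min(best, cost)
    return best


def flood_fill_count(binary: np.ndarray, min_area: int = 1,
                     max_area: int | None = None) -> int:
    """8-connectivity component count by explicit BFS flood fill."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    h, w = binary.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            area = 0
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if area >= min_area and (max_area is None or area <= max_area):
                count += 1
    return count
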