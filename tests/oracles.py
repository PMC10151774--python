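"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (per-point ray walks, explicit BFS,
O(n^2) pair counting, hand-rolled Kabsch SVD) and shares no code with the
package, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

_DIRECTIONS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


def psp_counts_bruteforce(occupancy: np.ndarray) -> np.ndarray:
    """Per-point PSP counts by walking every ray step by step."""
    dims = occupancy.shape
    psp = np.zeros(dims, dtype=int)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                if occupancy[i, j, k]:
                    continue
                count = 0
                for d in _DIRECTIONS:
                    if _ray_hits(occupancy, (i, j, k), d) and _ray_hits(
                        occupancy, (i, j, k), tuple(-c for c in d)
                    ):
                        count += 1
                psp[i, j, k] = count
    return psp


def _ray_hits(occ: np.ndarray, start, d) -> bool:
    i, j, k = start
    while True:
        i, j, k = i + d[0], j + d[1], k + d[2]
        if not (0 <= i < occ.shape[0] and 0 <= j < occ.shape[1] and 0 <= k < occ.shape[2]):
            return False
        if occ[i, j, k]:
            return True


def pockets_bruteforce(occupancy: np.ndarray, min_psp: int, min_cluster_size: int):
    """Pocket clusters by BFS over face-adjacent buried points.

    Returns a list of (point set, min flat index) sorted like the
    implementation: volume (size) descending, then smallest flat index.
    """
    psp = psp_counts_bruteforce(occupancy)
    dims = occupancy.shape
    eligible = {
        (i, j, k)
        for i in range(dims[0])
        for j in range(dims[1])
        for k in range(dims[2])
        if not occupancy[i, j, k] and psp[i, j, k] >= min_psp
    }
    clusters = []
    seen = set()
    for seed_pt in sorted(eligible):
        if seed_pt in seen:
            continue
        frontier = [seed_pt]
        members = set()
        while frontier:
            p = frontier.pop()
            if p in members:
                continue
            members.add(p)
            for axis in range(3):
                for step in (-1, 1):
                    q = list(p)
                    q[axis] += step
                    q = tuple(q)
                    if q in eligible and q not in members:
                        frontier.append(q)
        seen |= members
        if len(members) >= min_cluster_size:
            flat = min(np.ravel_multi_index(p, dims) for p in members)
            clusters.append((members, flat))
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return clusters


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD over rigid superposition via the classic Kabsch SVD."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    r = u @ d @ vt
    return float(np.sqrt(np.mean(np.sum((b @ r - a) ** 2, axis=1))))


def kendall_tau_b_bruteforce(x, y) -> float:
    """Tie-corrected tau by explicit O(n^2) pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    concordant = discordant = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx == dy:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tie_x) * (n0 - tie_y))
    return float((concordant - discordant) / denom)
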