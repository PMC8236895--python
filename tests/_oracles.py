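"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the k-means oracle
enumerates interval partitions of the sorted samples, and the
connected-components oracle is a breadth-first flood fill over explicit
neighbor offsets.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def kmeans_bruteforce_objective(samples: np.ndarray, k: int) -> float:
    """Global minimum of the k-means objective for 1-D samples.

    Optimal 1-D squared-loss partitions are intervals of the sorted
    sample, so enumerating the C(n-1, k-1) split placements is exhaustive.
    """
    x = np.sort(np.asarray(samples, dtype=np.float64).ravel())
    n = x.size
    k = min(k, np.unique(x).size)

    def interval_cost(lo: int, hi: int) -> float:  # half-open [lo, hi)
        seg = x[lo:hi]
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        cost = sum(interval_cost(bounds[i], bounds[i + 1]) for i in range(k))
        best = min(best, cost)
    return best


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    max_nonzero = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        nz = sum(1 for v in d if v != 0)
        if 1 <= nz <= max_nonzero:
            offsets.append(d)
    return offsets


def flood_fill_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS connected-component labeling; components numbered in raster-scan
    order of first encounter."""
    mask = np.asarray(mask, dtype=bool)
    offsets = _neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        count += 1
        labels[start] = count
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz_, ny_, nx_ = z + dz, y + dy, x + dx
                if (
                    0 <= nz_ < mask.shape[0]
                    and 0 <= ny_ < mask.shape[1]
                    and 0 <= nx_ < mask.shape[2]
                    and mask[nz_, ny_, nx_]
                    and not labels[nz_, ny_, nx_]
                ):
                    labels[nz_, ny_, nx_] = count
                    queue.append((nz_, ny_, nx_))
    return labels, count


def fill_holes_bruteforce(mask: np.ndarray, connectivity_background: int) -> np.ndarray:
    """Hole filling via the background flood-fill oracle: any background
    component containing no border voxel becomes foreground."""
    mask = np.asarray(mask, dtype=bool)
    labels, count = flood_fill_components(~mask, connectivity_background)
    border = np.zeros(mask.shape, dtype=bool)
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border[tuple(sl)] = True
    border_ids = set(np.unique(labels[border & ~mask]).tolist()) - {0}
    out = mask.copy()
    for cid in range(1, count + 1):
        if cid not in border_ids:
            out |= labels == cid
    return out
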