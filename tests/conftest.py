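"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid scipy/skimage morphology and assignment
routines: dilation/erosion are computed over explicit coordinate sets,
connected components by breadth-first flood fill, and instance matching by
exhaustive enumeration over all one-to-one assignments. They are slow and
only used on small volumes/tables, as ground truth for the fast paths.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from mitometrics import InstanceVolume


# ---------------------------------------------------------------------------
# coordinate-set morphology oracles


def dilate_oracle(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """{p + d : p in mask, d in {-r..r}^3} intersected with the volume bounds."""
    out = np.zeros_like(mask, dtype=bool)
    offsets = list(itertools.product(range(-radius, radius + 1), repeat=3))
    for p in np.argwhere(mask):
        for d in offsets:
            q = p + d
            if all(0 <= q[a] < mask.shape[a] for a in range(3)):
                out[tuple(q)] = True
    return out


def erode_oracle(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Voxels whose full box neighborhood (clipped nowhere) lies inside the mask."""
    out = np.zeros_like(mask, dtype=bool)
    offsets = list(itertools.product(range(-radius, radius + 1), repeat=3))
    for p in np.argwhere(mask):
        ok = True
        for d in offsets:
            q = p + d
            if not all(0 <= q[a] < mask.shape[a] for a in range(3)) or not mask[tuple(q)]:
                ok = False
                break
        out[tuple(p)] = ok
    return out


_NEIGHBORS = {
    6: [d for d in itertools.product((-1, 0, 1), repeat=3) if sum(map(abs, d)) == 1],
    18: [d for d in itertools.product((-1, 0, 1), repeat=3) if 0 < sum(map(abs, d)) <= 2],
    26: [d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)],
}


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> int:
    """Connected-component count by breadth-first flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            for d in _NEIGHBORS[connectivity]:
                q = tuple(p[a] + d[a] for a in range(3))
                if (
                    all(0 <= q[a] < mask.shape[a] for a in range(3))
                    and mask[q]
                    and not seen[q]
                ):
                    seen[q] = True
                    queue.append(q)
    return count


def dci_oracle(labels: np.ndarray, instance_id: int, radius: int = 1) -> int:
    """Distinct other labels intersecting the dilated coordinate set."""
    dilated = dilate_oracle(labels == instance_id, radius)
    touched = set(np.unique(labels[dilated]).tolist())
    return len(touched - {0, instance_id})


def efi_oracle(labels: np.ndarray, instance_id: int, radius: int = 1,
               connectivity: int = 26) -> int:
    eroded = erode_oracle(labels == instance_id, radius)
    return max(0, bfs_components(eroded, connectivity) - 1)


# ---------------------------------------------------------------------------
# assignment oracle


def best_assignment_total(iou: np.ndarray) -> float:
    """Maximum total IoU over all one-to-one assignments (factorial enumeration)."""
    n_g, n_p = iou.shape
    if n_g == 0 or n_p == 0:
        return 0.0
    if n_g <= n_p:
        cols = range(n_p)
        return max(
            sum(iou[r, c] for r, c in enumerate(perm))
            for perm in itertools.permutations(cols, n_g)
        )
    rows = range(n_g)
    return max(
        sum(iou[r, c] for c, r in enumerate(perm))
        for perm in itertools.permutations(rows, n_p)
    )


def matching_counts_oracle(iou: np.ndarray, tau: float) -> tuple[int, int, int]:
    """(TP, FP, FN) from the maximum-total-IoU assignment, then tau filtering.

    Enumerates all one-to-one assignments, takes the one with the largest
    total IoU (unique almost surely for continuous random tables), and counts
    its pairs with IoU >= tau. Mirrors the assign-then-threshold order of the
    fast path without sharing any code with it.
    """
    n_g, n_p = iou.shape
    best_total, best_tp = -1.0, 0
    if n_g and n_p:
        if n_g <= n_p:
            candidates = (
                list(enumerate(perm)) for perm in itertools.permutations(range(n_p), n_g)
            )
        else:
            candidates = (
                [(r, c) for c, r in enumerate(perm)]
                for perm in itertools.permutations(range(n_g), n_p)
            )
        for pairs in candidates:
            total = sum(iou[r, c] for r, c in pairs)
            if total > best_total:
                best_total = total
                best_tp = sum(iou[r, c] >= tau for r, c in pairs)
    else:
        best_tp = 0
    return best_tp, n_p - best_tp, n_g - best_tp


# ---------------------------------------------------------------------------
# random labeled volumes


def random_volume(seed: int, shape=(20, 20, 20), max_instances: int = 10) -> InstanceVolume:
    """Random labeled volume: overlapping random boxes, later boxes overwrite.

    Produces irregular, possibly multi-part instances — good stress input for
    the morphology oracles. Instance count is at most ``max_instances``.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int64)
    n = int(rng.integers(1, max_instances + 1))
    for i in range(1, n + 1):
        size = rng.integers(2, 7, size=3)
        corner = [int(rng.integers(0, s - z + 1)) for s, z in zip(shape, size)]
        sl = tuple(slice(c, c + int(z)) for c, z in zip(corner, size))
        labels[sl] = i
    return InstanceVolume(labels=labels, spacing=(16.0, 16.0, 16.0), name=f"rand{seed}")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
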