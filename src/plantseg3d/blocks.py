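"""Whole-plant → fixed-size block preprocessing.

A scanned plant is far larger than the number of points the network ingests
at once, so it is cut into spatially coherent blocks of roughly
``target_points`` points each.  The procedure:

1. voxel-grid partition at a resolution chosen (by bisection) so the median
   occupied-voxel population is close to ``target_points``;
2. greedy merging of adjacent under-populated voxel groups, so block sizes
   become as uniform as possible while staying spatially contiguous;
3. median-plane splitting (along the longest extent axis) of any group that
   exceeds ``2 * target_points``.

The result is a partition: every source point lands in exactly one block.
Blocks are later resampled to the exact network input size with
:func:`resample_block`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cloud import BlockSet, LabeledPointCloud
from .errors import ValidationError

__all__ = ["split_into_blocks", "resample_block"]


def _voxel_keys(coords: np.ndarray, origin: np.ndarray, s: float) -> np.ndarray:
    return np.floor((coords - origin) / s).astype(np.int64)


def _median_occupancy(coords, origin, s) -> float:
    keys = _voxel_keys(coords, origin, s)
    _, counts = np.unique(keys, axis=0, return_counts=True)
    return float(np.median(counts))


def _pick_voxel_size(coords: np.ndarray, target: int) -> float:
    """Bisect the voxel edge length until the median occupied-voxel
    population lands near ``target``."""
    origin = coords.min(axis=0)
    extent = coords.max(axis=0) - origin
    diag = float(np.linalg.norm(extent))
    if diag == 0.0:
        return 1.0
    lo, hi = diag / 512.0, diag * 1.01
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        med = _median_occupancy(coords, origin, mid)
        if 0.75 * target <= med <= 1.5 * target:
            return mid
        if med < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _Group:
    __slots__ = ("cells", "points")

    def __init__(self, cells: set[tuple], points: np.ndarray):
        self.cells = cells
        self.points = points

    @property
    def size(self) -> int:
        return len(self.points)

    def key(self) -> tuple:
        return min(self.cells)


def _adjacent(a: _Group, b: _Group) -> bool:
    # Chebyshev distance 1 between any pair of member voxels.
    for ca in a.cells:
        for cb in b.cells:
            if max(abs(ca[0] - cb[0]), abs(ca[1] - cb[1]), abs(ca[2] - cb[2])) <= 1:
                return True
    return False


def _median_split(points: np.ndarray, coords: np.ndarray, cap: int) -> list[np.ndarray]:
    """Recursively split a point-index set at the median plane of its longest
    axis until every piece has at most ``cap`` points."""
    if len(points) <= cap:
        return [points]
    sub = coords[points]
    axis = int(np.argmax(sub.max(axis=0) - sub.min(axis=0)))
    order = np.argsort(sub[:, axis], kind="stable")
    half = len(points) // 2
    left, right = points[order[:half]], points[order[half:]]
    return _median_split(left, coords, cap) + _median_split(right, coords, cap)


def split_into_blocks(plant: LabeledPointCloud, target_points: int = 2048,
                      min_points: int | None = None, plant_index: int = 0,
                      return_info: bool = False):
    """Partition a whole plant into spatially contiguous blocks.

    Every block ends up with a point count in ``[min_points, 2*target_points]``
    (default ``min_points = target_points // 4``) and every source point
    appears in exactly one block.

    A plant smaller than ``min_points`` is passed through as a single block
    with a warning.
    """
    if target_points < 1:
        raise ValidationError("target_points must be positive")
    if min_points is None:
        min_points = max(1, target_points // 4)
    if min_points > target_points:
        raise ValidationError("min_points cannot exceed target_points")
    coords = plant.coords
    n = plant.n
    if n < min_points:
        warnings.warn(
            f"plant has only {n} points (< min_points={min_points}); "
            "returning it as a single block")
        bs = BlockSet([plant.subset(np.arange(n))], [plant_index],
                      [np.arange(n)])
        return (bs, {"voxel_size": None}) if return_info else bs
    if n <= int(1.5 * target_points):
        bs = BlockSet([plant.subset(np.arange(n))], [plant_index],
                      [np.arange(n)])
        return (bs, {"voxel_size": None}) if return_info else bs

    s = _pick_voxel_size(coords, target_points)
    origin = coords.min(axis=0)
    keys = _voxel_keys(coords, origin, s)
    groups: list[_Group] = []
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for gi in range(len(uniq)):
        pts = np.nonzero(inverse == gi)[0]
        groups.append(_Group({tuple(uniq[gi])}, pts))

    # Greedy merging: consume small groups into adjacent neighbours, keeping
    # sizes near the target.  Soft cap 1.5*target for consistency merges;
    # merges required to reach min_points ignore the cap (phase-2 splitting
    # repairs any overshoot).
    soft_cap = int(1.5 * target_points)
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda g: (g.size, g.key()))
        for g in groups:
            if g.size >= target_points:
                continue
            neighbours = [o for o in groups if o is not g and _adjacent(g, o)]
            candidates = [o for o in neighbours if g.size + o.size <= soft_cap]
            pick = None
            if candidates:
                pick = min(candidates, key=lambda o: (o.size, o.key()))
            elif g.size < min_points:
                if neighbours:
                    pick = min(neighbours, key=lambda o: (o.size, o.key()))
                elif len(groups) > 1:
                    # isolated fragment: fall back to nearest-centroid merge
                    gc = coords[g.points].mean(axis=0)
                    pick = min(
                        (o for o in groups if o is not g),
                        key=lambda o: float(np.linalg.norm(
                            coords[o.points].mean(axis=0) - gc)))
            if pick is not None:
                pick.cells |= g.cells
                pick.points = np.sort(np.concatenate([pick.points, g.points]))
                groups.remove(g)
                changed = True
                break

    # Median-plane splitting of over-populated groups.
    cap = 2 * target_points
    pieces: list[np.ndarray] = []
    for g in sorted(groups, key=_Group.key):
        pieces.extend(_median_split(np.sort(g.points), coords, cap))

    bs = BlockSet([plant.subset(p) for p in pieces],
                  [plant_index] * len(pieces), list(pieces))
    if return_info:
        return bs, {"voxel_size": s}
    return bs


def resample_block(block: LabeledPointCloud, n_points: int = 2048,
                   seed: int | np.random.Generator = 0) -> LabeledPointCloud:
    """Resample a block to exactly ``n_points`` points.

    If the block has at least ``n_points`` points, a uniform subsample
    without replacement is drawn; otherwise every point is kept once and the
    remainder is drawn with replacement.  Labels travel with their points.
    Deterministic for a fixed seed.
    """
    if n_points < 1:
        raise ValidationError("n_points must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if block.n >= n_points:
        idx = rng.choice(block.n, size=n_points, replace=False)
    else:
        extra = rng.choice(block.n, size=n_points - block.n, replace=True)
        idx = np.concatenate([np.arange(block.n), extra])
    return block.subset(idx)
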