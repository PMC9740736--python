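"""Deterministic geometric primitives: farthest point sampling, ball query,
neighbourhood gathering.

All three are exact, brute-force computations (the package operates at desk
scale) with fully specified tie-breaking, so every downstream forward pass is
reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor
from .cloud import PointCloud
from .errors import ValidationError

__all__ = ["NeighborhoodIndex", "farthest_point_sample", "ball_query",
           "group_features"]


@dataclass
class NeighborhoodIndex:
    """Fixed-width neighbourhoods around a set of centre points.

    ``centers`` are indices into the source cloud; ``neighbor_idx[m, k]`` is
    the k-th neighbour of centre m (nearest first).  Neighbourhoods smaller
    than K are padded by repeating the centre index with
    ``valid_mask[m, k] = False``.
    """

    centers: np.ndarray          # (M,) int
    neighbor_idx: np.ndarray     # (M, K) int
    valid_mask: np.ndarray       # (M, K) bool

    @property
    def m(self) -> int:
        return len(self.centers)

    @property
    def k(self) -> int:
        return self.neighbor_idx.shape[1]


def farthest_point_sample(cloud: PointCloud | np.ndarray, m: int,
                          start_index: int = 0) -> np.ndarray:
    """Greedy max-min subsampling of ``m`` points.

    The first pick is ``start_index``; each subsequent pick maximises the
    minimum Euclidean distance to the points already picked, with ties broken
    by lowest index.  Deterministic.
    """
    coords = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(cloud)
    n = coords.shape[0]
    if not (1 <= m <= n):
        raise ValidationError(f"m={m} must be in [1, {n}]")
    if not (0 <= start_index < n):
        raise ValidationError(f"start_index {start_index} out of range")
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start_index
    # min distance from every point to the selected set
    d = np.linalg.norm(coords - coords[start_index], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(d))  # argmax returns the first (lowest) index on ties
        selected[i] = nxt
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return selected


def ball_query(cloud: PointCloud | np.ndarray, centers: np.ndarray,
               radius: float, k_max: int) -> NeighborhoodIndex:
    """Closed-ball neighbourhoods of up to ``k_max`` points per centre.

    Neighbours are ordered nearest-first with ties broken by lowest index;
    the centre itself (distance 0) is always a member.  Short neighbourhoods
    are padded with the centre index and masked invalid.
    """
    coords = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(cloud)
    centers = np.asarray(centers, dtype=np.int64)
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    m = len(centers)
    neighbor_idx = np.empty((m, k_max), dtype=np.int64)
    valid = np.zeros((m, k_max), dtype=bool)
    if m == 0:
        return NeighborhoodIndex(centers, neighbor_idx, valid)
    dists = cdist(coords[centers], coords)
    for row, c in enumerate(centers):
        inside = np.nonzero(dists[row] <= radius)[0]
        order = inside[np.lexsort((inside, dists[row, inside]))]
        if c not in order[:k_max]:       # possible only with >k_max duplicates
            order = np.concatenate(([c], order[order != c]))
        take = order[:k_max]
        neighbor_idx[row, :len(take)] = take
        neighbor_idx[row, len(take):] = c
        valid[row, :len(take)] = True
    return NeighborhoodIndex(centers, neighbor_idx, valid)


def group_features(features, nbr: NeighborhoodIndex):
    """Gather per-point features into an (M, K, C) neighbourhood tensor.

    ``out[m, k, :] = features[nbr.neighbor_idx[m, k], :]``; padded slots carry
    the centre's feature (their index is the centre).  Accepts a NumPy array
    or an autodiff :class:`~plantseg3d.autodiff.Tensor` (gradients flow back
    through the gather).
    """
    idx = nbr.neighbor_idx
    n_feat = features.shape[0]
    if idx.size and (idx.min() < 0 or idx.max() >= n_feat):
        raise ValidationError("neighbor indices out of range for feature matrix")
    if isinstance(features, Tensor):
        flat = features[idx.reshape(-1)]
        return flat.reshape(idx.shape[0], idx.shape[1], features.shape[1])
    return np.asarray(features)[idx]
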