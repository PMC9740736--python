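"""Neighbourhood position coding.

Each ball-query neighbourhood is summarised by two learnable codes that are
concatenated per centre point:

* **RPC** (relative position code): the centre-minus-neighbour coordinate
  offsets, mapped pointwise through a small MLP and max-pooled over the
  valid neighbours.  Exactly translation-invariant and invariant to the
  ordering of neighbours within the ball.
* **APC** (absolute position code): the centre's own (block-local)
  coordinates through a second, independent MLP.  Deliberately *not*
  translation-invariant — it anchors features in the block frame.

The two MLPs do not share weights: they consume different semantics
(offsets vs. coordinates).  An optional flag additionally feeds the centre
coordinate into the RPC branch alongside each offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .cloud import PointCloud
from .errors import ConfigError
from .geometry import NeighborhoodIndex
from .layers import MLP

__all__ = ["PositionCode", "relative_codes", "encode_positions"]

_NEG = -1e30  # pool mask fill; smaller than any real activation


@dataclass
class PositionCode:
    """Per-centre position features: RPC block, APC block, concatenation."""

    rpc_features: Tensor   # (M, C_r)
    apc_features: Tensor   # (M, C_a)
    combined: Tensor       # (M, C_r + C_a)


def relative_codes(cloud: PointCloud | np.ndarray,
                   nbr: NeighborhoodIndex) -> np.ndarray:
    """Centre-minus-neighbour offsets, (M, K, 3); padded slots are zero.

    A point's offset to itself is the zero vector, so the code is exactly
    invariant to rigid translation of the whole cloud.
    """
    coords = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(cloud)
    out = coords[nbr.centers][:, None, :] - coords[nbr.neighbor_idx]
    out[~nbr.valid_mask] = 0.0
    return out


def masked_max_pool(x: Tensor, valid_mask: np.ndarray) -> Tensor:
    """Max over axis 1, restricted to valid slots (slot 0 — the centre — is
    always valid, so the pool is never empty)."""
    mask = valid_mask.astype(np.float64)
    shaped = mask[:, :, None]
    return (x * shaped + (1.0 - shaped) * _NEG).max(axis=1)


def encode_positions(cloud: PointCloud | np.ndarray, nbr: NeighborhoodIndex,
                     theta_rpc: MLP, theta_apc: MLP,
                     include_center_in_rpc: bool = False) -> PositionCode:
    """Compute the position code of every neighbourhood.

    ``theta_rpc`` maps each 3-d offset (6-d if ``include_center_in_rpc``) to
    C_r features which are max-pooled over the valid neighbours;
    ``theta_apc`` maps the centre coordinate to C_a features.  The result is
    invariant to neighbour ordering (symmetric pool) and the RPC block is
    invariant to translation.
    """
    if theta_rpc is None or theta_apc is None:
        raise ConfigError("position-code MLPs are not initialized")
    coords = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(cloud)
    rel = relative_codes(coords, nbr)                    # (M, K, 3)
    if include_center_in_rpc:
        ctr = np.broadcast_to(coords[nbr.centers][:, None, :], rel.shape)
        rel = np.concatenate([ctr, rel], axis=2)         # (M, K, 6)
    m, k, c_in = rel.shape
    per_slot = theta_rpc(Tensor(rel.reshape(m * k, c_in))) \
        .reshape(m, k, -1)                               # (M, K, C_r)
    rpc = masked_max_pool(per_slot, nbr.valid_mask)      # (M, C_r)
    apc = theta_apc(Tensor(coords[nbr.centers]))         # (M, C_a)
    return PositionCode(rpc, apc, concat([rpc, apc], axis=1))
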