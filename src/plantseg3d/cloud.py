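"""Core containers: point clouds, labelled point clouds, block sets.

Labels follow the fixed organ encoding ``flower=0, leaf=1, stem=2``.
Coordinates are kept exactly as read; centring/normalisation is an explicit
pipeline step so file round-trips stay lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Fixed organ label encoding used everywhere in the package.
FLOWER, LEAF, STEM = 0, 1, 2
CLASS_NAMES = ("flower", "leaf", "stem")
N_CLASSES = 3


@dataclass
class PointCloud:
    """An unordered set of N points in 3-space.

    ``coords`` is an N×3 float array in consistent (arbitrary) spatial units.
    """

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"coords must be N×3, got shape {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValidationError("point cloud must contain at least one point")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class LabeledPointCloud:
    """A point cloud with an optional per-point organ label.

    ``labels`` is either ``None`` (unlabelled cloud) or a length-N integer
    vector with values in ``{0=flower, 1=leaf, 2=stem}``.
    """

    cloud: PointCloud
    labels: np.ndarray | None = None

    def __post_init__(self):
        if not isinstance(self.cloud, PointCloud):
            self.cloud = PointCloud(np.asarray(self.cloud))
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.dtype.kind not in "iu":
                if not np.all(self.labels == np.round(self.labels)):
                    raise ValidationError("labels must be integers")
                self.labels = self.labels.astype(np.int64)
            else:
                self.labels = self.labels.astype(np.int64)
            if self.labels.shape != (self.cloud.n,):
                raise ValidationError(
                    f"labels length {self.labels.shape} != point count {self.cloud.n}")
            bad = (self.labels < 0) | (self.labels >= N_CLASSES)
            if bad.any():
                raise ValidationError(
                    f"unknown label values {sorted(set(self.labels[bad].tolist()))}; "
                    f"expected 0..{N_CLASSES - 1}")

    @property
    def coords(self) -> np.ndarray:
        return self.cloud.coords

    @property
    def n(self) -> int:
        return self.cloud.n

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def subset(self, idx: np.ndarray) -> "LabeledPointCloud":
        idx = np.asarray(idx)
        return LabeledPointCloud(
            PointCloud(self.coords[idx]),
            None if self.labels is None else self.labels[idx])


@dataclass
class BlockSet:
    """A collection of blocks cut from one or more source plants.

    ``provenance[i]`` is the index of the plant that block ``i`` came from.
    """

    blocks: list[LabeledPointCloud] = field(default_factory=list)
    provenance: list[int] = field(default_factory=list)
    #: optional per-block index arrays into the source plant (set by the
    #: block splitter; empty when blocks were built some other way)
    source_indices: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.blocks) != len(self.provenance):
            raise ValidationError("blocks and provenance lengths differ")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def extend(self, blocks, plant_index: int):
        for b in blocks:
            self.blocks.append(b)
            self.provenance.append(plant_index)

    @property
    def total_points(self) -> int:
        return sum(b.n for b in self.blocks)


def center_and_scale(block: LabeledPointCloud):
    """Subtract the centroid and scale to unit radius.

    Returns ``(normalized_block, centroid, scale)`` so that predictions can be
    mapped back:  original = normalized * scale + centroid.
    """
    c = block.coords.mean(axis=0)
    shifted = block.coords - c
    r = float(np.linalg.norm(shifted, axis=1).max())
    if r == 0.0:
        r = 1.0
    return (LabeledPointCloud(PointCloud(shifted / r), block.labels), c, r)
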