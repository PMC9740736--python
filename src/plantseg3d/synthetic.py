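"""Procedural labelled plant point clouds.

The generator emulates the structure that makes plant organ segmentation
hard: thin tubular stems winding through the scene, broad gently-bent
leaves, and dense petal clusters (flowers) at stem tips, all interwoven and
noisy.  Geometry is parametric-surface sampling — random cubic-spline tubes,
bent elliptical patches, unions of petal patches — not botanical simulation:
the goal is ground-truth-labelled interwoven thin/flat/clustered structure,
generated deterministically from a seed, not visual realism.

``interleave`` ∈ [0, 1] controls entanglement: at 1 organs sit where they
naturally attach (bounding boxes overlap); at 0 every organ instance is
moved to its own cell of a well-separated grid (pairwise margins greater
than twice the noise level); intermediate values interpolate linearly.

Whole plants are split into train/test *by plant* (never by block), then
block-split and resampled to the configured input size.  A manifest records
every per-plant seed and spec, so a dataset can be regenerated bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.interpolate import CubicSpline

from .blocks import resample_block, split_into_blocks
from .cloud import BlockSet, FLOWER, LEAF, STEM, LabeledPointCloud, PointCloud
from .errors import ValidationError

__all__ = ["PlantSpec", "generate_plant", "generate_dataset",
           "regenerate_dataset", "DatasetResult"]


@dataclass
class PlantSpec:
    """Parameters of one synthetic plant.

    Lengths are in the plant's arbitrary spatial unit (stems are O(1) long).
    ``points_per_*`` are uniform-integer ranges per organ instance.
    """

    n_stems: int = 3
    stem_length: tuple = (0.7, 1.1)
    stem_curvature: tuple = (0.10, 0.35)
    stem_radius: float = 0.012
    n_leaves: int = 5
    leaf_size: tuple = (0.10, 0.18)
    n_flowers: int = 3
    flower_radius: float = 0.055
    points_per_stem: tuple = (120, 180)
    points_per_leaf: tuple = (110, 170)
    points_per_flower: tuple = (100, 150)
    interleave: float = 0.7
    noise_sd: float = 0.004
    seed: int = 0

    def __post_init__(self):
        if min(self.n_stems, self.n_leaves, self.n_flowers) < 0:
            raise ValidationError("organ counts must be non-negative")
        if self.n_stems + self.n_leaves + self.n_flowers == 0:
            raise ValidationError("at least one organ must be present")
        if self.n_stems == 0 and (self.n_leaves or self.n_flowers):
            raise ValidationError("leaves/flowers need a stem to attach to")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 0.0 <= self.interleave <= 1.0:
            raise ValidationError("interleave must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlantSpec":
        d = dict(d)
        for k in ("stem_length", "stem_curvature", "leaf_size",
                  "points_per_stem", "points_per_leaf", "points_per_flower"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _unit(v):
    return v / (np.linalg.norm(v) + 1e-12)


def _frame(tangent):
    """Two unit vectors orthogonal to ``tangent`` and each other."""
    t = _unit(tangent)
    ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n1 = _unit(np.cross(t, ref))
    return n1, np.cross(t, n1)


def _stem_curve(rng, base, direction, length, curvature):
    """Random cubic-spline space curve from ``base`` along ``direction``."""
    n_ctrl = 5
    ts = np.linspace(0.0, 1.0, n_ctrl)
    d = _unit(direction)
    n1, n2 = _frame(d)
    wiggle = rng.normal(0.0, curvature * length / 3.0, size=(n_ctrl, 2))
    wiggle[0] = 0.0
    ctrl = (base[None, :] + ts[:, None] * length * d[None, :]
            + wiggle[:, :1] * n1[None, :] + wiggle[:, 1:] * n2[None, :])
    return CubicSpline(ts, ctrl, axis=0)


def _sample_tube(rng, spline, radius, n):
    ts = rng.uniform(0.0, 1.0, n)
    centers = spline(ts)
    tangents = spline(ts, 1)
    pts = np.empty((n, 3))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    for i in range(n):
        n1, n2 = _frame(tangents[i])
        pts[i] = centers[i] + radius * (np.cos(phi[i]) * n1 + np.sin(phi[i]) * n2)
    return pts


def _sample_leaf(rng, attach, size, n):
    """Bent elliptical patch whose base touches ``attach``."""
    az = rng.uniform(0.0, 2 * np.pi)
    pitch = rng.uniform(-0.5, 0.6)
    e1 = _unit(np.array([np.cos(az) * np.cos(pitch),
                         np.sin(az) * np.cos(pitch), np.sin(pitch)]))
    n1, n2 = _frame(e1)
    e2, e3 = n1, n2
    a, b = size, 0.5 * size
    bend = rng.uniform(0.1, 0.4) * size
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    p, q = a * r * np.cos(phi), b * r * np.sin(phi)
    center = attach + a * e1
    return (center[None, :] + p[:, None] * e1[None, :] + q[:, None] * e2[None, :]
            + (bend * ((p / a) ** 2 + (q / b) ** 2))[:, None] * e3[None, :])


def _sample_flower(rng, center, radius, n):
    """Union of 5–8 tilted petal patches around a stem tip."""
    n_petals = int(rng.integers(5, 9))
    counts = np.full(n_petals, n // n_petals)
    counts[: n % n_petals] += 1
    pts = []
    for i in range(n_petals):
        az = 2 * np.pi * i / n_petals + rng.normal(0.0, 0.15)
        tilt = rng.uniform(0.35, 1.05)     # radians up from horizontal
        d = np.array([np.cos(az) * np.cos(tilt), np.sin(az) * np.cos(tilt),
                      np.sin(tilt)])
        pc = center + 0.6 * radius * d
        e1 = _unit(d)
        e2, _ = _frame(e1)
        a, b = 0.55 * radius, 0.3 * radius
        r = np.sqrt(rng.uniform(0.0, 1.0, counts[i]))
        phi = rng.uniform(0.0, 2 * np.pi, counts[i])
        pts.append(pc[None, :] + (a * r * np.cos(phi))[:, None] * e1[None, :]
                   + (b * r * np.sin(phi))[:, None] * e2[None, :])
    return np.vstack(pts)


def generate_plant(spec: PlantSpec, return_geometry: bool = False):
    """Generate one labelled plant cloud (deterministic for a fixed seed).

    With ``return_geometry=True`` also returns a dict holding each stem's
    densely sampled centre polyline (after organ placement), the per-organ
    point slices, and the organ displacement applied by ``interleave``.
    """
    rng = np.random.default_rng(spec.seed)
    organs = []        # (label, points, extra)

    stem_splines = []
    main = _stem_curve(rng, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                       rng.uniform(*spec.stem_length),
                       rng.uniform(*spec.stem_curvature))
    stem_splines.append(main)
    for _ in range(1, spec.n_stems):
        t0 = rng.uniform(0.2, 0.8)
        base = main(t0)
        direction = _unit(np.array([rng.normal(), rng.normal(),
                                    abs(rng.normal()) + 0.8]))
        stem_splines.append(_stem_curve(
            rng, base, direction,
            rng.uniform(*spec.stem_length) * rng.uniform(0.5, 0.9),
            rng.uniform(*spec.stem_curvature)))
    for sp in stem_splines:
        n = int(rng.integers(*spec.points_per_stem))
        organs.append((STEM, _sample_tube(rng, sp, spec.stem_radius, n),
                       {"polyline": sp(np.linspace(0, 1, 400))}))

    for _ in range(spec.n_leaves):
        sp = stem_splines[int(rng.integers(len(stem_splines)))]
        attach = sp(rng.uniform(0.15, 0.95))
        n = int(rng.integers(*spec.points_per_leaf))
        organs.append((LEAF, _sample_leaf(rng, attach,
                                          rng.uniform(*spec.leaf_size), n), {}))

    for i in range(spec.n_flowers):
        sp = stem_splines[i % len(stem_splines)]
        n = int(rng.integers(*spec.points_per_flower))
        organs.append((FLOWER, _sample_flower(rng, sp(1.0),
                                              spec.flower_radius, n), {}))

    # interleave: blend between the natural (attached) layout and a
    # well-separated grid layout
    f = spec.interleave
    offsets = [np.zeros(3)] * len(organs)
    if f < 1.0 and len(organs) > 1:
        extents = [pts.max(axis=0) - pts.min(axis=0) for _, pts, _ in organs]
        pitch = float(max(e.max() for e in extents)) + 4.0 * spec.noise_sd + 0.1
        side = int(np.ceil(len(organs) ** (1.0 / 3.0)))
        offsets = []
        for i, (_, pts, _) in enumerate(organs):
            cell = np.array([i % side, (i // side) % side, i // side ** 2],
                            dtype=float) * pitch
            offsets.append((1.0 - f) * (cell - pts.mean(axis=0)))

    coords_parts, labels_parts, geometry = [], [], {"stems": [], "slices": []}
    start = 0
    for (label, pts, extra), off in zip(organs, offsets):
        pts = pts + off
        coords_parts.append(pts)
        labels_parts.append(np.full(len(pts), label, dtype=np.int64))
        geometry["slices"].append((label, slice(start, start + len(pts))))
        if "polyline" in extra:
            geometry["stems"].append(extra["polyline"] + off)
        start += len(pts)
    coords = np.vstack(coords_parts)
    labels = np.concatenate(labels_parts)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    plant = LabeledPointCloud(PointCloud(coords), labels)
    return (plant, geometry) if return_geometry else plant


@dataclass
class DatasetResult:
    train: BlockSet
    test: BlockSet
    manifest: dict
    plants: list = field(default_factory=list)


def _jittered_spec(base: PlantSpec, rng: np.random.Generator,
                   seed: int) -> PlantSpec:
    d = base.to_dict()
    d["seed"] = seed
    d["n_leaves"] = max(0, base.n_leaves + int(rng.integers(-1, 2)))
    d["n_flowers"] = max(1, base.n_flowers + int(rng.integers(-1, 2)))
    s = float(rng.uniform(0.9, 1.1))
    d["leaf_size"] = [v * s for v in d["leaf_size"]]
    d["flower_radius"] = base.flower_radius * s
    return PlantSpec.from_dict(d)


def generate_dataset(n_plants: int, base_spec: PlantSpec | None = None,
                     seed: int = 0, test_fraction: float = 2.0 / 11.0,
                     target_points: int = 2048, min_points: int | None = None,
                     n_points: int = 2048, jitter: bool = True) -> DatasetResult:
    """Generate a blocked train/test dataset of synthetic plants.

    Plants are assigned to train or test as whole plants (no plant ever
    contributes blocks to both sides); each plant is block-split at
    ``target_points`` and every block resampled to exactly ``n_points``.
    The default ``test_fraction`` mirrors a 9:2 whole-plant split.
    """
    if n_plants < 2:
        raise ValidationError("need at least 2 plants for a train/test split")
    base = base_spec or PlantSpec()
    rng = np.random.default_rng(seed)
    n_test = max(1, round(n_plants * test_fraction))
    if n_test >= n_plants:
        raise ValidationError("test fraction leaves no training plants")
    order = rng.permutation(n_plants)
    test_ids = set(order[:n_test].tolist())
    plant_entries = []
    for i in range(n_plants):
        pseed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _jittered_spec(base, rng, pseed) if jitter else \
            PlantSpec.from_dict({**base.to_dict(), "seed": pseed})
        plant_entries.append({"spec": spec.to_dict(),
                              "split": "test" if i in test_ids else "train",
                              "block_seed": int(rng.integers(0, 2 ** 31 - 1))})
    manifest = {"format": "plantseg3d-dataset-v1", "seed": int(seed),
                "n_plants": int(n_plants), "target_points": int(target_points),
                "min_points": min_points, "n_points": int(n_points),
                "plants": plant_entries}
    return regenerate_dataset(manifest)


def regenerate_dataset(manifest: dict) -> DatasetResult:
    """Rebuild a dataset exactly from its manifest."""
    train, test = BlockSet(), BlockSet()
    plants = []
    for i, entry in enumerate(manifest["plants"]):
        spec = PlantSpec.from_dict(entry["spec"])
        plant = generate_plant(spec)
        plants.append(plant)
        bs = split_into_blocks(plant, target_points=manifest["target_points"],
                               min_points=manifest["min_points"],
                               plant_index=i)
        brng = np.random.default_rng(entry["block_seed"])
        resampled = [resample_block(b, manifest["n_points"], brng)
                     for b in bs.blocks]
        target = test if entry["split"] == "test" else train
        target.extend(resampled, i)
    return DatasetResult(train, test, manifest, plants)
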