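"""Point-cloud file I/O.

Two formats:

* ``xyz`` — whitespace-separated ASCII columns ``x y z [label]``; ``#``
  starts a comment; blank lines ignored.
* ``ply`` — PLY vertex clouds with properties ``x, y, z`` and an optional
  integer ``label``; ASCII and binary_little_endian 1.0 are both read and
  written.  Coordinates are stored as float64 so binary round-trips are
  bitwise exact.

Block sets are persisted as a directory of per-block ``.xyz`` files plus a
JSON manifest (``blocks.json``) recording provenance.
"""

from __future__ import annotations

import json
import os
import struct
from pathlib import Path

import numpy as np

from .cloud import BlockSet, LabeledPointCloud, PointCloud
from .errors import ParseError, ValidationError

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("ply", "xyz"):
            raise ValidationError(f"unknown format {fmt!r}; expected 'ply' or 'xyz'")
        return fmt
    suffix = Path(path).suffix.lower()
    return "ply" if suffix == ".ply" else "xyz"


# ---------------------------------------------------------------------------
# xyz ASCII
# ---------------------------------------------------------------------------

def _read_xyz(path) -> LabeledPointCloud:
    coords, labels = [], []
    n_cols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ParseError(
                    f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {n_cols})")
            try:
                xyz = [float(v) for v in parts[:3]]
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad coordinate: {e}") from None
            coords.append(xyz)
            if n_cols == 4:
                try:
                    lab = int(parts[3])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: label {parts[3]!r} is not an integer"
                    ) from None
                labels.append(lab)
    if not coords:
        raise ParseError(f"{path}: no points found")
    return LabeledPointCloud(
        PointCloud(np.array(coords)),
        np.array(labels) if labels else None)


def _write_xyz(cloud: LabeledPointCloud, path):
    with open(path, "w") as fh:
        fh.write("# x y z" + (" label" if cloud.has_labels else "") + "\n")
        for i in range(cloud.n):
            x, y, z = cloud.coords[i]
            line = f"{x:.10g} {y:.10g} {z:.10g}"
            if cloud.has_labels:
                line += f" {cloud.labels[i]}"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

def _read_ply(path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        props: list[tuple[str, str]] = []
        n_vertices = None
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unexpected EOF in header")
            tokens = line.decode("ascii", "replace").strip().split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ParseError(f"{path}: list properties not supported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertices is None:
            raise ParseError(f"{path}: no vertex element")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ParseError(f"{path}: vertex property {axis!r} missing")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertices):
                line = fh.readline()
                if not line:
                    raise ParseError(f"{path}: vertex {i}: unexpected EOF")
                parts = line.split()
                if len(parts) != len(props):
                    raise ParseError(
                        f"{path}: vertex {i}: expected {len(props)} values, "
                        f"got {len(parts)}")
                rows.append([float(v) for v in parts])
            table = {name: np.array([r[j] for r in rows])
                     for j, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + _PLY_DTYPES[t]) for name, t in props])
            buf = fh.read(dtype.itemsize * n_vertices)
            if len(buf) != dtype.itemsize * n_vertices:
                raise ParseError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dtype)
            table = {name: rec[name] for name, _ in props}
    coords = np.column_stack([table["x"], table["y"], table["z"]]).astype(np.float64)
    labels = None
    if "label" in table:
        lab = np.asarray(table["label"])
        if not np.all(lab == np.round(lab)):
            raise ParseError(f"{path}: non-integer label values")
        labels = lab.astype(np.int64)
    return LabeledPointCloud(PointCloud(coords), labels)


def _write_ply(cloud: LabeledPointCloud, path, binary: bool):
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0",
              f"element vertex {cloud.n}",
              "property double x", "property double y", "property double z"]
    if cloud.has_labels:
        header.append("property int label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            for i in range(cloud.n):
                fh.write(struct.pack("<3d", *cloud.coords[i]))
                if cloud.has_labels:
                    fh.write(struct.pack("<i", int(cloud.labels[i])))
        else:
            for i in range(cloud.n):
                x, y, z = (float(v) for v in cloud.coords[i])
                line = f"{x!r} {y!r} {z!r}"
                if cloud.has_labels:
                    line += f" {cloud.labels[i]}"
                fh.write((line + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def read_point_cloud(path, fmt: str | None = None) -> LabeledPointCloud:
    """Read a point cloud (with labels if the file has them).

    ``fmt`` is ``"ply"`` or ``"xyz"``; when omitted it is inferred from the
    file suffix (``.ply`` → PLY, anything else → ASCII xyz).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"{path}: no such file")
    return _read_ply(path) if _infer_format(path, fmt) == "ply" else _read_xyz(path)


def write_point_cloud(cloud: LabeledPointCloud, path, fmt: str | None = None,
                      binary: bool = True):
    """Write a point cloud; PLY defaults to binary_little_endian."""
    path = os.fspath(path)
    if _infer_format(path, fmt) == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        _write_xyz(cloud, path)


def save_block_set(bs: BlockSet, directory):
    """Persist a block set as ``block_00000.xyz`` files + ``blocks.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, block in enumerate(bs.blocks):
        name = f"block_{i:05d}.xyz"
        _write_xyz(block, directory / name)
        names.append(name)
    manifest = {"format": "plantseg3d-blockset-v1",
                "files": names, "provenance": list(map(int, bs.provenance))}
    (directory / "blocks.json").write_text(json.dumps(manifest, indent=1))


def load_block_set(directory) -> BlockSet:
    directory = Path(directory)
    manifest_path = directory / "blocks.json"
    if not manifest_path.exists():
        raise ParseError(f"{directory}: blocks.json not found")
    manifest = json.loads(manifest_path.read_text())
    blocks = [_read_xyz(directory / name) for name in manifest["files"]]
    return BlockSet(blocks, manifest["provenance"])
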