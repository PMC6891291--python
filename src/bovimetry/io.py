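"""ASCII point-cloud readers and writers (PCD v0.7, PLY 1.0, XYZ).

Only the ASCII dialects are supported: the test fixtures and the feature
database must be bit-exact text, and every consumer in this package works in
float64 meters. Writing is deterministic — the same cloud written twice
produces identical bytes. NaN rows (common in organized range images, where
invalid pixels are stored as NaN) are dropped on read with a logged count.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np

from .cloud import PointCloud
from .errors import EmptyCloudError, ParameterError

logger = logging.getLogger(__name__)

_FORMATS = ("pcd", "ply", "xyz")

# 12 significant digits: lossless well below the 1e-6 m round-trip contract.
_FMT = "{:.12g}"


def _format_row(row: np.ndarray) -> str:
    return " ".join(_FMT.format(v) for v in row)


def write_pointcloud(cloud: PointCloud, path: str | os.PathLike, format: str = "pcd") -> str:
    """Write *cloud* to *path* in the given ASCII format; returns the path."""
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}, expected one of {_FORMATS}")
    pts = cloud.points
    n = pts.shape[0]
    lines: list[str] = []
    if format == "pcd":
        lines += [
            "# .PCD v0.7 - Point Cloud Data file format",
            "VERSION 0.7",
            "FIELDS x y z",
            "SIZE 4 4 4",
            "TYPE F F F",
            "COUNT 1 1 1",
            f"WIDTH {n}",
            "HEIGHT 1",
            "VIEWPOINT 0 0 0 1 0 0 0",
            f"POINTS {n}",
            "DATA ascii",
        ]
    elif format == "ply":
        lines += [
            "ply",
            "format ascii 1.0",
            f"element vertex {n}",
            "property float x",
            "property float y",
            "property float z",
            "end_header",
        ]
    lines.extend(_format_row(row) for row in pts)
    text = "\n".join(lines) + "\n"
    with open(path, "w", newline="\n") as fh:
        fh.write(text)
    return os.fspath(path)


def _parse_rows(rows: Iterable[str], path) -> np.ndarray:
    data = []
    for line in rows:
        parts = line.split()
        if not parts:
            continue
        data.append([float(parts[0]), float(parts[1]), float(parts[2])])
    arr = np.asarray(data, dtype=np.float64).reshape(-1, 3)
    finite = np.all(np.isfinite(arr), axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("dropped %d non-finite row(s) while reading %s", dropped, path)
    arr = arr[finite]
    if arr.shape[0] == 0:
        raise EmptyCloudError(f"no finite points in {path}")
    return arr


def _read_pcd(path) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_expected = None
    data_start = None
    for i, line in enumerate(lines):
        token = line.split("#")[0].strip()
        if not token:
            continue
        key = token.split()[0].upper()
        if key == "POINTS":
            n_expected = int(token.split()[1])
        elif key == "DATA":
            mode = token.split()[1].lower()
            if mode != "ascii":
                raise ParameterError(f"only ASCII PCD is supported, got DATA {mode}")
            data_start = i + 1
            break
    if data_start is None:
        raise ParameterError(f"{path}: missing DATA line; not a valid PCD header")
    rows = lines[data_start:]
    if n_expected is not None:
        rows = rows[:n_expected]
    return _parse_rows(rows, path)


def _read_ply(path) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParameterError(f"{path}: not a PLY file")
    n_vertex = None
    props: list[str] = []
    in_vertex = False
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            if parts[1] != "ascii":
                raise ParameterError(f"only ASCII PLY is supported, got {parts[1]}")
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n_vertex = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            props.append(parts[-1])
        elif parts[0] == "end_header":
            body_start = i + 1
            break
    if body_start is None or n_vertex is None:
        raise ParameterError(f"{path}: malformed PLY header")
    try:
        cols = [props.index(c) for c in ("x", "y", "z")]
    except ValueError as exc:
        raise ParameterError(f"{path}: PLY vertex element lacks x/y/z") from exc
    data = []
    for line in lines[body_start:body_start + n_vertex]:
        parts = line.split()
        if not parts:
            continue
        data.append([float(parts[c]) for c in cols])
    return _parse_rows((" ".join(map(str, r)) for r in data), path)


def read_pointcloud(path: str | os.PathLike, format: str | None = None) -> PointCloud:
    """Read an ASCII point-cloud file.

    The format is taken from *format* or inferred from the file extension.
    Non-finite rows are dropped (their count is logged); a file with zero
    finite points raises :class:`~bovimetry.errors.EmptyCloudError`.
    """
    if format is None:
        format = os.path.splitext(os.fspath(path))[1].lstrip(".").lower()
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}, expected one of {_FORMATS}")
    if format == "pcd":
        pts = _read_pcd(path)
    elif format == "ply":
        pts = _read_ply(path)
    else:
        with open(path) as fh:
            pts = _parse_rows(fh.read().splitlines(), path)
    return PointCloud(pts)
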