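"""Affine silhouette augmentation: seven yaw rotations plus two mirrors.

Each source cloud is expanded to ten: the original, clockwise rotations of
45..315 degrees in 45-degree steps about the vertical (height) axis through
the cloud centroid, a horizontal mirror (reflection across the sagittal xy
plane) and a vertical mirror (reflection across the transverse yz plane).
All nine derived variants are rigid or reflecting, so they preserve every
pairwise distance — and hence all true body dimensions.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import PointCloud
from .errors import ParameterError
from .io import read_pointcloud, write_pointcloud

logger = logging.getLogger(__name__)

ROTATION_ANGLES_DEG = (45, 90, 135, 180, 225, 270, 315)


@dataclass
class AffineTransform:
    """A 3x3 linear map applied to every point of a cloud."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ParameterError(f"matrix must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ParameterError("singular matrix is not a valid augmentation")
        self.matrix = m

    @property
    def is_rotation(self) -> bool:
        m = self.matrix
        return (np.allclose(m @ m.T, np.eye(3), atol=1e-9)
                and np.linalg.det(m) > 0)

    @property
    def is_mirror(self) -> bool:
        m = self.matrix
        return (np.allclose(m @ m.T, np.eye(3), atol=1e-9)
                and np.linalg.det(m) < 0)


def clockwise_rotation_y(angle_deg: float) -> AffineTransform:
    """Clockwise rotation about the vertical (y) axis.

    Convention: clockwise 90 degrees maps (1, 0, 0) to (0, 0, -1).
    """
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return AffineTransform(np.array([[c, 0.0, s],
                                     [0.0, 1.0, 0.0],
                                     [-s, 0.0, c]]))


def horizontal_mirror() -> AffineTransform:
    """Reflection across the sagittal (xy) plane: z -> -z."""
    return AffineTransform(np.diag([1.0, 1.0, -1.0]))


def vertical_mirror() -> AffineTransform:
    """Reflection across the transverse (yz) plane: x -> -x."""
    return AffineTransform(np.diag([-1.0, 1.0, 1.0]))


def affine_transform(cloud: PointCloud, t: AffineTransform,
                     about_centroid: bool = True) -> PointCloud:
    """Apply the map to every point, by default about the cloud centroid."""
    pts = cloud.points
    if about_centroid:
        c = pts.mean(axis=0)
        out = (pts - c) @ t.matrix.T + c
    else:
        out = pts @ t.matrix.T
    return PointCloud(out, frame_id=cloud.frame_id)


#: Suffixes of the nine derived variants, in deterministic output order.
VARIANT_SUFFIXES = tuple(f"_r{a:03d}" for a in ROTATION_ANGLES_DEG) + ("_mh", "_mv")


def augment_cloud(cloud: PointCloud) -> list[PointCloud]:
    """The original plus its nine variants, in deterministic order."""
    out = [cloud]
    for angle in ROTATION_ANGLES_DEG:
        out.append(affine_transform(cloud, clockwise_rotation_y(angle)))
    out.append(affine_transform(cloud, horizontal_mirror()))
    out.append(affine_transform(cloud, vertical_mirror()))
    return out


def augment_dataset(clouds: list[PointCloud]) -> list[PointCloud]:
    """Ten-fold expansion: each original followed by its nine variants."""
    if not clouds:
        raise ParameterError("input cloud list is empty")
    out: list[PointCloud] = []
    for c in clouds:
        out.extend(augment_cloud(c))
    logger.info("augmentation: %d -> %d clouds", len(clouds), len(out))
    return out


def augment_files(in_dir: str | os.PathLike, out_dir: str | os.PathLike,
                  format: str = "pcd") -> list[str]:
    """Augment every ``*.format`` file in *in_dir* into *out_dir*.

    Each input ``name.ext`` yields ``name.ext`` plus nine suffixed variants
    (``name_r045.ext`` ... ``name_mv.ext``). Returns the written paths.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    files = sorted(in_dir.glob(f"*.{format}"))
    if not files:
        raise ParameterError(f"no *.{format} files in {in_dir}")
    for f in files:
        cloud = read_pointcloud(f, format)
        variants = augment_cloud(cloud)
        names = [f.stem] + [f.stem + sfx for sfx in VARIANT_SUFFIXES]
        for name, var in zip(names, variants):
            path = out_dir / f"{name}.{format}"
            write_pointcloud(var, path, format)
            written.append(str(path))
    logger.info("augmented %d files -> %d files", len(files), len(written))
    return written
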