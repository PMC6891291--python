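"""The point-cloud container shared by every pipeline stage.

Coordinates are metric meters throughout. A cloud is an *ordered* list of
points: several downstream rules (first-match landmark recognition in
particular) are defined in terms of the stored point order, so operations
that filter a cloud preserve the order of the surviving points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyCloudError


@dataclass
class PointCloud:
    """An ordered set of 3D points in meters.

    Parameters
    ----------
    points
        Array-like of shape (n, 3). Coordinates must be finite.
    frame_id
        Coordinate convention label: ``"sensor"`` for raw acquisition
        coordinates, ``"normalized"`` for the body-aligned canonical frame.
    """

    points: np.ndarray
    frame_id: str = "sensor"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 1:
            raise EmptyCloudError("a point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, indices) -> "PointCloud":
        """Sub-cloud at the given indices, order as given."""
        return PointCloud(self.points[np.asarray(indices)], frame_id=self.frame_id)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    frame_id: str | None = None) -> "PointCloud":
        """Apply ``p -> R p + t`` to every point."""
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=np.float64).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=np.float64)
        return PointCloud(pts, frame_id=self.frame_id if frame_id is None else frame_id)

    def copy(self) -> "PointCloud":
        return PointCloud(self.points.copy(), frame_id=self.frame_id)
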