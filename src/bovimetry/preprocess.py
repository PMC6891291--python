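"""Filtering fusion: conditional range filter, statistical outlier removal,
voxel downsampling — applied in that order.

The conditional filter crops the working volume, the statistical filter
removes isolated range outliers (mixed pixels, reflections), and the voxel
filter compresses the cloud to roughly uniform density. No filter ever
invents points except the voxel filter, whose outputs are per-cell
centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Parameters of the three-stage filter fusion.

    ``ranges`` maps axis index (0=x, 1=y, 2=z) to closed ``(min, max)``
    bounds in meters; unbounded axes are simply absent. ``knn_k`` and
    ``alpha`` control the statistical filter (keep a point iff its mean
    distance to its k nearest neighbors is within ``alpha`` standard
    deviations of the global mean of those per-point means). ``leaf`` is the
    voxel edge length.
    """

    ranges: dict = field(default_factory=lambda: {0: (-4.0, 4.0),
                                                  1: (-0.5, 3.0),
                                                  2: (-4.0, 4.0)})
    knn_k: int = 8
    alpha: float = 1.0
    leaf: float = 0.02

    def validate(self) -> None:
        for ax, (lo, hi) in self.ranges.items():
            if ax not in (0, 1, 2):
                raise ParameterError(f"axis index {ax} not in (0, 1, 2)")
            if not lo < hi:
                raise ParameterError(f"axis {ax}: min {lo} must be < max {hi}")
        if self.knn_k < 1:
            raise ParameterError("knn_k must be >= 1")
        if self.leaf <= 0:
            raise ParameterError("leaf must be > 0")


def conditional_filter(cloud: PointCloud, ranges: dict) -> PointCloud | None:
    """Keep exactly the points inside all closed per-axis intervals.

    Order is preserved. Returns ``None`` (with a logged warning) when no
    point survives — an empty working volume is a data condition, not a bug.
    """
    if not ranges:
        raise ParameterError("at least one axis must be bounded")
    mask = np.ones(len(cloud), dtype=bool)
    for ax, (lo, hi) in ranges.items():
        mask &= (cloud.points[:, ax] >= lo) & (cloud.points[:, ax] <= hi)
    n_kept = int(mask.sum())
    logger.info("conditional filter: %d -> %d points", len(cloud), n_kept)
    if n_kept == 0:
        logger.warning("conditional filter removed every point")
        return None
    return cloud.select(np.nonzero(mask)[0])


def statistical_outlier_removal(cloud: PointCloud, knn_k: int = 8,
                                alpha: float = 1.0) -> PointCloud:
    """Remove points whose k-NN mean distance is anomalously large.

    A point is kept iff its mean distance to its ``knn_k`` nearest neighbors
    is <= mean + alpha * std of those per-point means over the whole cloud
    (ties at the threshold are kept).
    """
    n = len(cloud)
    if knn_k >= n:
        raise ParameterError(f"knn_k ({knn_k}) must be < cloud size ({n})")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=knn_k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + alpha * mean_d.std()
    mask = mean_d <= thresh
    logger.info("statistical filter: %d -> %d points", n, int(mask.sum()))
    return cloud.select(np.nonzero(mask)[0])


def voxel_downsample(cloud: PointCloud, leaf: float) -> PointCloud:
    """Replace all points in each occupied voxel by their centroid.

    Voxel index = floor(coordinate / leaf) per axis; output cells are
    ordered lexicographically by voxel index, which keeps the stored point
    order deterministic for the downstream first-match landmark rule.
    """
    if leaf <= 0:
        raise ParameterError("leaf must be > 0")
    idx = np.floor(cloud.points / leaf).astype(np.int64)
    # lexicographic cell order (z fastest)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    sorted_idx = idx[order]
    uniq, start, counts = np.unique(sorted_idx, axis=0, return_index=True,
                                    return_counts=True)
    sums = np.add.reduceat(cloud.points[order], start, axis=0)
    centroids = sums / counts[:, None]
    logger.info("voxel filter (leaf %.3g): %d -> %d points",
                leaf, len(cloud), len(centroids))
    return PointCloud(centroids, frame_id=cloud.frame_id)


def preprocess(cloud: PointCloud, params: FilterParams | None = None) -> PointCloud:
    """Run the full filter fusion: conditional -> statistical -> voxel."""
    p = params or FilterParams()
    p.validate()
    out = conditional_filter(cloud, p.ranges)
    if out is None:
        raise ParameterError("conditional filter left no points; widen the ranges")
    if len(out) > p.knn_k:
        out = statistical_outlier_removal(out, p.knn_k, p.alpha)
    return voxel_downsample(out, p.leaf)
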