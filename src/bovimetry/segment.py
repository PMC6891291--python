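"""Subject isolation: RANSAC ground-plane extraction followed by Euclidean
cluster extraction.

The ground touches the animal's hooves, so distance-based clustering alone
cannot separate the two — the plane is therefore removed *first*, and the
largest remaining cluster is taken as the subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import DegenerateModelError, ParameterError, SegmentationError

logger = logging.getLogger(__name__)


@dataclass
class PlaneModel:
    """A fitted plane ``normal . p + offset = 0`` with its inlier set."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise DegenerateModelError("plane normal must be non-zero")
        self.normal = n / norm
        self.offset = float(self.offset) / norm

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distances of points to the plane."""
        return points @ self.normal + self.offset

    def oriented_towards(self, point: np.ndarray) -> "PlaneModel":
        """Copy with the normal pointing towards *point* (positive side)."""
        if self.distance(np.asarray(point)[None, :])[0] < 0:
            return PlaneModel(-self.normal, -self.offset, self.inlier_indices)
        return self


def euclidean_cluster(cloud: PointCloud, tol: float, min_size: int = 1,
                      max_size: int | None = None) -> list[np.ndarray]:
    """Connected components of the graph linking points within *tol*.

    Components outside ``[min_size, max_size]`` are discarded; the surviving
    clusters are returned largest-first (ties broken by smallest member
    index, so the partition is independent of point order).
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    n = len(cloud)
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if pairs.size:
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    n_comp, comp = connected_components(graph, directed=False)
    clusters = []
    for c in range(n_comp):
        idx = np.nonzero(comp == c)[0]
        if len(idx) < min_size:
            continue
        if max_size is not None and len(idx) > max_size:
            continue
        clusters.append(idx)
    clusters.sort(key=lambda ix: (-len(ix), int(ix[0])))
    if not clusters:
        logger.warning("no cluster within size range [%s, %s]", min_size, max_size)
    else:
        logger.info("euclidean clustering: %d clusters, sizes %s", len(clusters),
                    [len(c) for c in clusters[:5]])
    return clusters


def _fit_plane_lsq(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through a point set (smallest PCA axis)."""
    centroid = points.mean(axis=0)
    q = points - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if points.shape[0] >= 3 and s[1] < 1e-12 * max(s[0], 1e-300):
        raise DegenerateModelError("points are (near-)collinear; plane undefined")
    normal = vt[2]
    return normal, -float(normal @ centroid)


def ransac_plane(cloud: PointCloud, dist_thresh: float = 0.02,
                 max_iter: int = 500, seed: int = 0) -> PlaneModel:
    """Best-consensus plane over seeded 3-point hypotheses, refit to inliers.

    Ties on inlier count go to the earlier iteration. The final model is a
    total-least-squares refit on the winning hypothesis' inliers, with the
    inlier set recomputed once against the refit plane.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ParameterError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    best_count = -1
    best_mask = None
    for _ in range(max_iter):
        idx = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        d = np.abs((pts - p0) @ normal)
        mask = d <= dist_thresh
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
    if best_mask is None:
        raise DegenerateModelError("all sampled triples were collinear")
    normal, offset = _fit_plane_lsq(pts[best_mask])
    final = np.abs(pts @ normal + offset) <= dist_thresh
    model = PlaneModel(normal, offset, np.nonzero(final)[0])
    logger.info("RANSAC plane: %d/%d inliers, normal %s", len(model.inlier_indices),
                n, np.round(model.normal, 4))
    return model


@dataclass
class SegmentParams:
    plane_dist_thresh: float = 0.02
    plane_max_iter: int = 500
    cluster_tol: float = 0.06
    cluster_min_size: int = 50
    cluster_max_size: int | None = None


def extract_subject(cloud: PointCloud, params: SegmentParams | None = None,
                    seed: int = 0) -> tuple[PointCloud, PlaneModel]:
    """Isolate the animal: remove the ground plane, keep the largest cluster.

    Returns the subject sub-cloud (stored order preserved) and the fitted
    ground plane, which later serves as the height reference.
    """
    p = params or SegmentParams()
    ground = ransac_plane(cloud, p.plane_dist_thresh, p.plane_max_iter, seed)
    keep = np.ones(len(cloud), dtype=bool)
    keep[ground.inlier_indices] = False
    remaining = np.nonzero(keep)[0]
    if remaining.size == 0:
        raise SegmentationError("every point was a ground-plane inlier")
    rest = cloud.select(remaining)
    clusters = euclidean_cluster(rest, p.cluster_tol, p.cluster_min_size,
                                 p.cluster_max_size)
    if not clusters:
        raise SegmentationError("no cluster within the configured size range")
    subject_idx = remaining[clusters[0]]
    logger.info("subject: %d points (of %d after ground removal)",
                len(subject_idx), len(remaining))
    return cloud.select(subject_idx), ground
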