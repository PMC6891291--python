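"""Canonical pose and curvature analysis.

Pose normalization puts a segmented body cloud into a body-aligned frame:
origin at the centroid, x = body length (largest-variance axis), y = height,
z = chest width, right-handed. The x sign is then fixed by the orientation
rule: the half containing the withers (the higher of the two halves'
maximum heights) is the head half and is placed on -x, so the tail points
to +x; at most one sagittal mirror is applied.

Curvature analysis fits a local quadric height field to each point's
neighborhood and derives principal, mean (H) and Gaussian (K) curvatures.
The sign pair (sign H, sign K) types the local surface into eight realizable
shapes (peak, ridge, saddle ridge, plane, minimal saddle, valley, saddle
valley, well); H ~ 0 with K > 0 cannot occur on a real surface because
K <= H^2 always. Normals are oriented away from the body centroid, so
convex body regions (back line, brisket, bosses) get H > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (DegeneratePoseError, ImpossibleSurfaceTypeError,
                     ParameterError)

logger = logging.getLogger(__name__)


class AmbiguousFrameWarning(UserWarning):
    """The covariance spectrum is (near-)degenerate; axes are not unique."""


# ---------------------------------------------------------------------------
# canonical frame
# ---------------------------------------------------------------------------

def compute_centroid(cloud: PointCloud) -> np.ndarray:
    """Arithmetic mean of the point coordinates."""
    return cloud.points.mean(axis=0)


def compute_covariance(cloud: PointCloud, centroid: np.ndarray | None = None
                       ) -> np.ndarray:
    """Covariance of the point set with 1/n normalization."""
    if len(cloud) < 2:
        raise ParameterError("covariance needs at least 2 points")
    c = compute_centroid(cloud) if centroid is None else np.asarray(centroid)
    q = cloud.points - c
    return (q.T @ q) / len(cloud)


@dataclass
class CanonicalFrame:
    """Body-aligned frame: rows of ``axes`` are (x=length, y=height, z=width)."""

    origin: np.ndarray
    axes: np.ndarray          # (3, 3), orthonormal rows, right-handed
    eigenvalues: np.ndarray   # descending

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (points - self.origin) @ self.axes.T

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return points @ self.axes + self.origin


def pca_frame(cov: np.ndarray, centroid: np.ndarray) -> CanonicalFrame:
    """Eigen-frame of the covariance, axes sorted by descending eigenvalue.

    Right-handedness is enforced by flipping the last axis if needed. Emits
    :class:`AmbiguousFrameWarning` when the two leading eigenvalues (or all
    three) are nearly equal, in which case the axis assignment is arbitrary.
    """
    cov = np.asarray(cov, dtype=np.float64)
    vals, vecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    axes = vecs[:, order].T               # rows e0, e1, e2
    scale = max(vals[0], 1e-300)
    if (vals[0] - vals[1]) / scale < 1e-6:
        warnings.warn("leading eigenvalues nearly equal; length/height axes "
                      "ambiguous", AmbiguousFrameWarning, stacklevel=2)
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return CanonicalFrame(origin=np.asarray(centroid, dtype=np.float64),
                          axes=axes, eigenvalues=np.clip(vals, 0.0, None))


def normalize_pose(cloud: PointCloud, up_hint: np.ndarray | None = None
                   ) -> tuple[PointCloud, CanonicalFrame]:
    """Rotate/translate a subject cloud into the body-aligned frame.

    With *up_hint* (e.g. the ground-plane normal pointing towards the
    animal) the height axis is taken as the hint direction itself and the
    length axis as the horizontal projection of the leading principal axis:
    the body's neck/head mass pitches the raw principal axis by several
    degrees, and the height measurements are defined perpendicular to the
    ground, so gravity wins over the covariance spectrum when it is known.
    Without a hint the pure PCA axes are used and the height sign is
    resolved by extent asymmetry: the legs reach much farther below the
    torso's center of mass than the back line rises above it, so the side
    of the centroid with the larger extent is taken as *down*. The x sign
    is left to :func:`orientation_correct`.
    """
    centroid = compute_centroid(cloud)
    frame = pca_frame(compute_covariance(cloud, centroid), centroid)
    axes = frame.axes.copy()
    if up_hint is not None:
        up = np.asarray(up_hint, dtype=np.float64)
        up = up / np.linalg.norm(up)
        e0 = axes[0] - (axes[0] @ up) * up
        norm0 = np.linalg.norm(e0)
        if norm0 < 1e-9:
            raise DegeneratePoseError("principal axis parallel to the up hint")
        axes[0] = e0 / norm0
        axes[1] = up
    else:
        proj = (cloud.points - centroid) @ axes[1]
        if proj.max() > -proj.min():
            axes[1] = -axes[1]
    axes[2] = np.cross(axes[0], axes[1])  # restore right-handedness
    frame = CanonicalFrame(origin=frame.origin, axes=axes,
                           eigenvalues=frame.eigenvalues)
    out = PointCloud(frame.to_frame(cloud.points), frame_id="normalized")
    return out, frame


MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def orientation_correct(cloud: PointCloud) -> tuple[PointCloud, bool]:
    """Place the head half on -x (tail on +x); returns (cloud, mirrored?).

    The head half is identified as the half (split at x = 0) whose maximum
    height is greater — the withers rise above everything on the rear half.
    Exactly zero or one sagittal mirror (x -> -x) is applied.
    """
    x = cloud.points[:, 0]
    q1 = x > 0
    q2 = x < 0
    if not q1.any() or not q2.any():
        raise DegeneratePoseError("one x half-space is empty; cannot orient")
    hmax_pos = cloud.points[q1, 1].max()
    hmax_neg = cloud.points[q2, 1].max()
    if hmax_pos > hmax_neg:
        return PointCloud(cloud.points @ MIRROR_X.T,
                          frame_id=cloud.frame_id), True
    return cloud, False


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def normal_curvature_euler(k1: float, k2: float, theta: float) -> float:
    """Normal curvature in the direction at angle *theta* from the k1 axis."""
    if k1 < k2:
        raise ParameterError("principal curvatures must satisfy k1 >= k2")
    return k1 * np.cos(theta) ** 2 + k2 * np.sin(theta) ** 2


def mean_gaussian_curvature(k1: float, k2: float) -> tuple[float, float]:
    """Mean H = (k1 + k2)/2 and Gaussian K = k1 * k2."""
    if k1 < k2:
        raise ParameterError("principal curvatures must satisfy k1 >= k2")
    return (k1 + k2) / 2.0, k1 * k2


class SurfaceType(Enum):
    SADDLE_VALLEY = "saddle_valley"   # H < 0, K < 0
    VALLEY = "valley"                 # H < 0, K = 0
    WELL = "well"                     # H < 0, K > 0
    PLANE = "plane"                   # H = 0, K = 0
    MINIMAL_SADDLE = "minimal_saddle" # H = 0, K < 0
    SADDLE_RIDGE = "saddle_ridge"     # H > 0, K < 0
    RIDGE = "ridge"                   # H > 0, K = 0
    PEAK = "peak"                     # H > 0, K > 0


_TYPE_TABLE = {
    (-1, -1): SurfaceType.SADDLE_VALLEY,
    (-1, 0): SurfaceType.VALLEY,
    (-1, 1): SurfaceType.WELL,
    (0, 0): SurfaceType.PLANE,
    (0, -1): SurfaceType.MINIMAL_SADDLE,
    (1, -1): SurfaceType.SADDLE_RIDGE,
    (1, 0): SurfaceType.RIDGE,
    (1, 1): SurfaceType.PEAK,
}


def classify_surface_type(H: float, K: float, eps_H: float, eps_K: float
                          ) -> SurfaceType:
    """Map (sign H, sign K) to one of the eight realizable surface types.

    Values within +-eps of zero count as zero. The ninth sign combination,
    H = 0 with K > 0, contradicts K <= H^2 and raises
    :class:`ImpossibleSurfaceTypeError`.
    """
    if eps_H <= 0 or eps_K <= 0:
        raise ParameterError("eps thresholds must be > 0")
    sh = 0 if abs(H) <= eps_H else (1 if H > 0 else -1)
    sk = 0 if abs(K) <= eps_K else (1 if K > 0 else -1)
    if sh == 0 and sk > 0:
        raise ImpossibleSurfaceTypeError(
            f"H ~ 0 with K = {K} > 0 is not attainable (K <= H^2)")
    return _TYPE_TABLE[(sh, sk)]


@dataclass
class CurvatureField:
    """Per-point curvature annotations on a (normalized) cloud.

    ``valid`` flags points whose neighborhood fit succeeded; invalid points
    carry NaN curvatures, no surface type, and are excluded from candidate
    regions.
    """

    k1: np.ndarray
    k2: np.ndarray
    H: np.ndarray
    K: np.ndarray
    surface_type: np.ndarray          # object array of SurfaceType or None
    valid: np.ndarray
    normals: np.ndarray
    mean_neighbor_radius: float
    eps_H: float = 0.0
    eps_K: float = 0.0


def estimate_normals(points: np.ndarray, knn_k: int = 16,
                     orient_away_from: np.ndarray | None = None,
                     tree: cKDTree | None = None) -> np.ndarray:
    """Local-PCA surface normals, oriented away from a reference point.

    The default reference is the cloud centroid: for a roughly convex body
    this yields consistently outward normals, the convention under which
    convex regions get positive mean curvature.
    """
    n = points.shape[0]
    if knn_k + 1 > n:
        raise ParameterError("knn_k must be smaller than the cloud")
    tree = tree or cKDTree(points)
    _, nbr = tree.query(points, k=knn_k + 1)
    neigh = points[nbr]                      # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]                  # smallest-eigenvalue axis
    ref = points.mean(axis=0) if orient_away_from is None else orient_away_from
    flip = np.einsum("ni,ni->n", normals, points - ref) < 0
    normals[flip] = -normals[flip]
    return normals


def principal_curvatures(cloud: PointCloud, knn_k: int = 16,
                         eps_H: float | None = None,
                         eps_K: float | None = None) -> CurvatureField:
    """Per-point principal/mean/Gaussian curvature by local quadric fitting.

    For each point, the ``knn_k``-neighborhood is expressed in a tangent
    frame (u, v, w) with w the outward normal, and a quadric
    ``w = a + b u + c v + d u^2 + e uv + f v^2`` is fit by least squares.
    The height-field first/second derivatives at the point (I_u = b,
    I_v = c, I_uu = 2d, I_uv = e, I_vv = 2f) give H and K through the
    first/second fundamental forms; the principal curvatures are recovered
    as ``H +- sqrt(max(0, H^2 - K))``.

    The zero-thresholds for surface typing default to 0.05 / r and
    0.01 / r^2, with r the mean neighborhood radius — dimensionless
    curvature thresholds scaled to the sampling resolution.
    """
    if knn_k < 6:
        raise ParameterError("knn_k must be >= 6 (a quadric has 6 coefficients)")
    pts = cloud.points
    n = len(pts)
    if knn_k + 1 > n:
        raise ParameterError("cloud smaller than the requested neighborhood")
    tree = cKDTree(pts)
    dist, nbr = tree.query(pts, k=knn_k + 1)
    normals = estimate_normals(pts, knn_k=knn_k, tree=tree)
    r_bar = float(dist[:, 1:].mean())
    if eps_H is None:
        eps_H = 0.05 / r_bar
    if eps_K is None:
        eps_K = 0.01 / r_bar ** 2

    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    Hs = np.full(n, np.nan)
    Ks = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    types = np.empty(n, dtype=object)

    # tangent bases: u orthogonal to the normal, v = w x u
    w = normals
    helper = np.where(np.abs(w[:, 0:1]) < 0.9,
                      np.tile([1.0, 0.0, 0.0], (n, 1)),
                      np.tile([0.0, 1.0, 0.0], (n, 1)))
    u = np.cross(w, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(w, u)

    rel = pts[nbr] - pts[:, None, :]         # (n, k+1, 3)
    lu = np.einsum("nkj,nj->nk", rel, u)
    lv = np.einsum("nkj,nj->nk", rel, v)
    lw = np.einsum("nkj,nj->nk", rel, w)

    for i in range(n):
        A = np.column_stack([np.ones(knn_k + 1), lu[i], lv[i],
                             lu[i] ** 2, lu[i] * lv[i], lv[i] ** 2])
        coef, _, rank, _ = np.linalg.lstsq(A, lw[i], rcond=None)
        if rank < 6:
            continue
        _, Iu, Iv, d, e, f = coef
        Iuu, Iuv, Ivv = 2 * d, e, 2 * f
        g = 1 + Iu ** 2 + Iv ** 2
        H = ((1 + Iu ** 2) * Ivv - 2 * Iu * Iv * Iuv
             + (1 + Iv ** 2) * Iuu) / (2 * g ** 1.5)
        K = (Iuu * Ivv - Iuv ** 2) / g ** 2
        # height increases along the outward normal; the fundamental-form H
        # of the height field is the curvature towards -w, so flip the sign
        # to make convex (bulging along +w) regions positive.
        H = -H
        disc = np.sqrt(max(0.0, H * H - K))
        k1[i], k2[i] = H + disc, H - disc
        Hs[i], Ks[i] = H, k1[i] * k2[i]
        valid[i] = True
        types[i] = classify_surface_type(Hs[i], Ks[i], eps_H, eps_K)

    logger.info("curvature: %d/%d points typed (r_bar %.3g, eps_H %.3g)",
                int(valid.sum()), n, r_bar, eps_H)
    return CurvatureField(k1=k1, k2=k2, H=Hs, K=Ks, surface_type=types,
                          valid=valid, normals=normals,
                          mean_neighbor_radius=r_bar, eps_H=eps_H, eps_K=eps_K)


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------

@dataclass
class LandmarkRule:
    """Where a landmark may live: surface types, length band, height band.

    ``t_band`` restricts candidates to a fraction band of the normalized
    body-length axis, with t = 0 at the muzzle (min x, head on -x after
    orientation correction) and t = 1 at the tail (max x). ``side``
    restricts to points above ("upper") or below ("lower") the centroid
    height. ``u_band`` restricts the normalized height u, defined as
    y / y_max above the centroid and -y / |y_min| below it (u = +1 at the
    withers crest, u = -1 at the hooves): the withers is by definition near
    the global height maximum, the back and loin are top-strip points, and
    the brisket sits in a known band between belly and hoof level. All
    three are anatomical priors expressed in pose-free coordinates.
    """

    types: frozenset
    t_band: tuple | None = None
    side: str | None = None
    u_band: tuple | None = None
    max_abs_z: float | None = None  # meters; landmarks sit on the midline


_CONVEX = frozenset({SurfaceType.PEAK, SurfaceType.RIDGE})

DEFAULT_LANDMARK_RULES = {
    "withers_upper": LandmarkRule(_CONVEX, (0.37, 0.46), "upper", (0.90, 1.0)),
    "chest_lower": LandmarkRule(frozenset({SurfaceType.PEAK, SurfaceType.VALLEY}),
                                (0.40, 0.48), "lower", (-0.50, -0.15)),
    "back_upper": LandmarkRule(_CONVEX, (0.54, 0.64), "upper", (0.82, 1.0)),
    "waist_upper": LandmarkRule(_CONVEX, (0.73, 0.84), "upper", (0.72, 1.0)),
    "bodylen_upper": LandmarkRule(_CONVEX, (0.22, 0.31), "upper", (0.45, 0.80)),
    "bodylen_lower": LandmarkRule(_CONVEX, (0.92, 0.985), "upper", (0.45, 0.80)),
}


def length_height_coords(cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Pose-free (t, u) coordinates of a normalized, oriented cloud.

    t runs 0 (muzzle) to 1 (tail) along x; u is the height normalized per
    side of the centroid: +1 at the crest (max y), -1 at the hooves.
    """
    x = cloud.points[:, 0]
    y = cloud.points[:, 1]
    span = max(x.max() - x.min(), 1e-12)
    t = (x - x.min()) / span
    y_max = max(y.max(), 1e-12)
    y_min = min(y.min(), -1e-12)
    u = np.where(y >= 0, y / y_max, y / -y_min)
    return t, u


def rules_from_priors(priors: dict, dt: float = 0.04, du: float = 0.04,
                      dz: float = 0.05, base: dict | None = None) -> dict:
    """Candidate rules centered on reference-animal landmark positions.

    ``priors`` maps landmark name to its mean (t, u) over the reference
    animals — optionally followed by the across-animal standard deviations
    (t_std, u_std) — recorded when the feature database is built. Band
    half-widths are the given ``dt``/``du`` floors widened to 3x the
    observed reference spread. The surface-type sets and centroid sides
    come from the base rules; only the bands are recalibrated. u bands
    crossing +-1 are clamped.
    """
    base = DEFAULT_LANDMARK_RULES if base is None else base
    out = {}
    for name, rule in base.items():
        if name in priors:
            vals = priors[name]
            t0, u0 = vals[0], vals[1]
            t_std = vals[2] if len(vals) > 2 else 0.0
            u_std = vals[3] if len(vals) > 3 else 0.0
            z_abs = vals[4] if len(vals) > 4 else None
            ht = max(dt, 3.0 * t_std)
            hu = max(du, 3.0 * u_std)
            out[name] = LandmarkRule(
                rule.types,
                (max(0.0, t0 - ht), min(1.0, t0 + ht)),
                rule.side,
                (max(-1.0, u0 - hu), min(1.0, u0 + hu)),
                None if z_abs is None else max(dz, 1.5 * z_abs))
        else:
            out[name] = rule
    return out


def candidate_regions(field_: CurvatureField, cloud: PointCloud,
                      mapping: dict | None = None) -> dict:
    """Per-landmark candidate index sets, in stored point order.

    A point is a candidate for a landmark when its surface type is allowed
    and it falls inside the landmark's length band and height side. Empty
    candidate sets are logged as a recognition-degraded warning (downstream
    matching will then fail for that landmark).
    """
    rules = DEFAULT_LANDMARK_RULES if mapping is None else mapping
    y = cloud.points[:, 1]
    t, u = length_height_coords(cloud)
    out = {}
    for name, rule in rules.items():
        mask = field_.valid.copy()
        type_ok = np.array([st in rule.types if st is not None else False
                            for st in field_.surface_type])
        mask &= type_ok
        if rule.t_band is not None:
            mask &= (t >= rule.t_band[0]) & (t <= rule.t_band[1])
        if rule.side == "upper":
            mask &= y > 0
        elif rule.side == "lower":
            mask &= y < 0
        if rule.u_band is not None:
            mask &= (u >= rule.u_band[0]) & (u <= rule.u_band[1])
        if rule.max_abs_z is not None:
            mask &= np.abs(cloud.points[:, 2]) <= rule.max_abs_z
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            logger.warning("empty candidate set for landmark %r "
                           "(recognition degraded)", name)
        out[name] = idx
    return out
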