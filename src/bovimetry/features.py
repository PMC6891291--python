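"""Fast Point Feature Histograms and the landmark feature-model database.

An FPFH descriptor summarizes the angular relations between a point's
normal and its neighborhood in 33 bins (3 Darboux-frame angles x 11 bins),
each 11-bin block normalized to sum 100. It is invariant under rigid
transforms, which lets reference descriptors recorded on one animal in one
pose recognize the same anatomical landmark on another scan.

Landmark recognition follows a first-match rule: candidates are scanned in
their stored order and the first one whose descriptor is within the match
threshold tau (L1 distance) of any reference descriptor for that landmark
wins; there is no global-best search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import DatabaseError, DescriptorError, LandmarkNotFoundError
from .geometry import estimate_normals
from .synth import LANDMARK_NAMES

logger = logging.getLogger(__name__)

N_BINS = 11
MIN_NEIGHBORS = 5


@dataclass
class FPFHDescriptor:
    """33 non-negative bins; each 11-bin block sums to 100."""

    bins: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.float64)
        if b.shape != (3 * N_BINS,):
            raise DescriptorError(f"expected {3 * N_BINS} bins, got {b.shape}")
        if np.any(b < 0):
            raise DescriptorError("bins must be non-negative")
        self.bins = b

    def distance(self, other: "FPFHDescriptor") -> float:
        """L1 distance between descriptors."""
        return float(np.abs(self.bins - other.bins).sum())


def _pair_features(ps, ns, pt, nt):
    """Darboux-frame angle features for source/target point+normal pairs."""
    d = pt - ps
    dist = np.linalg.norm(d, axis=-1)
    dist = np.where(dist == 0, 1.0, dist)
    dn = d / dist[..., None]
    u = ns
    v = np.cross(dn, u)
    vn = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / np.where(vn == 0, 1.0, vn)
    w = np.cross(u, v)
    alpha = np.einsum("...i,...i->...", v, nt)
    phi = np.einsum("...i,...i->...", u, dn)
    theta = np.arctan2(np.einsum("...i,...i->...", w, nt),
                       np.einsum("...i,...i->...", u, nt))
    return alpha, phi, theta


def _spfh(points, normals, i, neigh) -> np.ndarray:
    """Simplified histogram of point i against its neighbors (raw counts).

    The center point always acts as the Darboux-frame source: a
    smaller-angle source-selection rule would be discontinuous on locally
    symmetric patches, where sampling noise flips the choice and with it
    the signs of two of the three features. The theta block is circular
    (theta is an angle on the full circle).
    """
    ps, ns = points[i], normals[i]
    pt, nt = points[neigh], normals[neigh]
    alpha, phi, theta = _pair_features(np.broadcast_to(ps, pt.shape), ns,
                                       pt, nt)
    hist = np.zeros(3 * N_BINS)
    # linear (soft) binning: each sample splits its unit mass between the
    # two nearest bin centers. The common near-planar geometry puts theta
    # and alpha right on a hard-bin edge, where integer binning would
    # scatter counts on sampling noise.
    for k, (val, lo, hi, wrap) in enumerate(((alpha, -1.0, 1.0, False),
                                             (phi, -1.0, 1.0, False),
                                             (theta, -np.pi, np.pi, True))):
        c = (val - lo) / (hi - lo) * N_BINS - 0.5
        b0 = np.floor(c).astype(int)
        frac = c - b0
        if wrap:
            lo_bin = np.mod(b0, N_BINS)
            hi_bin = np.mod(b0 + 1, N_BINS)
        else:
            lo_bin = np.clip(b0, 0, N_BINS - 1)
            hi_bin = np.clip(b0 + 1, 0, N_BINS - 1)
        np.add.at(hist, k * N_BINS + lo_bin, 1.0 - frac)
        np.add.at(hist, k * N_BINS + hi_bin, frac)
    return hist


def compute_fpfh(cloud: PointCloud, index: int, radius: float,
                 normals: np.ndarray | None = None,
                 tree: cKDTree | None = None) -> FPFHDescriptor:
    """FPFH descriptor of one point of a cloud.

    FPFH(p) = SPFH(p) + (1/k) sum_j SPFH(p_j) / ||p - p_j||, followed by
    per-block percentage normalization. Raises
    :class:`~bovimetry.errors.DescriptorError` with fewer than 5 neighbors
    inside *radius*.
    """
    pts = cloud.points
    if normals is None:
        normals = estimate_normals(pts)
    tree = tree or cKDTree(pts)
    neigh = np.array(tree.query_ball_point(pts[index], radius))
    neigh = neigh[neigh != index]
    if neigh.size < MIN_NEIGHBORS:
        raise DescriptorError(
            f"point {index}: only {neigh.size} neighbors within {radius} m")
    hist = _spfh(pts, normals, index, neigh)
    acc = np.zeros_like(hist)
    for j in neigh:
        nj = np.array(tree.query_ball_point(pts[j], radius))
        nj = nj[nj != j]
        if nj.size == 0:
            continue
        w = np.linalg.norm(pts[j] - pts[index])
        if w == 0:
            continue
        acc += _spfh(pts, normals, j, nj) / w
    hist = hist + acc / neigh.size
    out = hist.reshape(3, N_BINS)
    sums = out.sum(axis=1, keepdims=True)
    sums = np.where(sums == 0, 1.0, sums)
    out = out / sums * 100.0
    return FPFHDescriptor(bins=out.ravel(), radius=radius)


@dataclass
class FeatureModelDB:
    """Reference FPFH descriptors per landmark plus the match threshold.

    ``landmark_priors`` optionally records each landmark's mean normalized
    (t, u) body position over the reference animals; when present, the
    pipeline centers the candidate-region bands on these positions instead
    of the coarse anatomical defaults.
    """

    entries: dict = field(default_factory=dict)
    tau: float = 0.0
    landmark_priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(LANDMARK_NAMES) - set(self.entries)
        extra = set(self.entries) - set(LANDMARK_NAMES)
        if missing or extra:
            raise DatabaseError(f"database must hold exactly the six landmarks; "
                                f"missing={sorted(missing)} extra={sorted(extra)}")
        if self.tau <= 0:
            raise DatabaseError("tau must be > 0")

    def save(self, path: str) -> str:
        arrays = {}
        meta = {"tau": self.tau, "landmarks": {},
                "priors": {k: [float(x) for x in v]
                           for k, v in self.landmark_priors.items()}}
        for name, descs in self.entries.items():
            meta["landmarks"][name] = {"count": len(descs),
                                       "radii": [d.radius for d in descs]}
            for i, d in enumerate(descs):
                arrays[f"{name}__{i}"] = d.bins
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str) -> "FeatureModelDB":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            entries = {}
            for name, info in meta["landmarks"].items():
                entries[name] = [
                    FPFHDescriptor(bins=data[f"{name}__{i}"], radius=r)
                    for i, r in enumerate(info["radii"])
                ]
        priors = {k: tuple(v) for k, v in meta.get("priors", {}).items()}
        return cls(entries=entries, tau=meta["tau"], landmark_priors=priors)


def calibrate_tau(entries: dict, groups: dict | None = None,
                  margin: float = 1.2, floor: float = 10.0) -> float:
    """Match threshold from reference self-consistency.

    With ``groups`` (parallel lists assigning each descriptor to its source
    animal), every reference simulates a query from an unseen animal: its
    leave-one-animal-out nearest-reference distance is what a matching pass
    would see. tau is margin x the 90th percentile of those simulated query
    distances (the percentile makes the estimate robust to a stray
    reference snapped onto an atypical sample). Without groups it falls
    back to margin x the largest pairwise distance within a landmark. The
    floor guards degenerate cases.
    """
    loo = []
    worst_pair = 0.0
    for name, descs in entries.items():
        grp = groups.get(name) if groups else None
        for i in range(len(descs)):
            if grp is not None:
                others = [descs[j].distance(descs[i]) for j in range(len(descs))
                          if grp[j] != grp[i]]
                if others:
                    loo.append(min(others))
                    continue
            for j in range(i + 1, len(descs)):
                worst_pair = max(worst_pair, descs[i].distance(descs[j]))
    bound = float(np.percentile(loo, 90)) if loo else worst_pair
    return max(margin * bound, floor)


def build_feature_db(examples: list, radius: float, tau: float | None = None,
                     ) -> FeatureModelDB:
    """Build the database from ``(landmark_name, cloud, point_index)`` tuples.

    Descriptors (and the normals they need) are computed per example cloud.
    With ``tau=None`` the threshold is calibrated from the references via
    :func:`calibrate_tau`.
    """
    entries: dict = {name: [] for name in LANDMARK_NAMES}
    groups: dict = {name: [] for name in LANDMARK_NAMES}
    cache: dict = {}
    for name, cloud, index in examples:
        if name not in entries:
            raise DatabaseError(f"unknown landmark name {name!r}")
        key = id(cloud)
        if key not in cache:
            tree = cKDTree(cloud.points)
            cache[key] = (estimate_normals(cloud.points, tree=tree), tree,
                          len(cache))
        normals, tree, group = cache[key]
        entries[name].append(compute_fpfh(cloud, index, radius,
                                          normals=normals, tree=tree))
        groups[name].append(group)
    empty = [n for n, d in entries.items() if not d]
    if empty:
        raise DatabaseError(f"no reference example for landmark(s) {empty}")
    if tau is None:
        tau = calibrate_tau(entries, groups)
    logger.info("feature DB: %d entries, tau = %.2f",
                sum(len(v) for v in entries.values()), tau)
    return FeatureModelDB(entries=entries, tau=tau)


def match_feature_point(candidates: np.ndarray, cloud: PointCloud,
                        landmark: str, db: FeatureModelDB, radius: float,
                        normals: np.ndarray | None = None,
                        tree: cKDTree | None = None) -> int:
    """First candidate (in stored order) within tau of any reference.

    Candidates whose descriptor cannot be computed (too few neighbors) are
    skipped. Raises :class:`~bovimetry.errors.LandmarkNotFoundError` when no
    candidate matches.
    """
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        raise LandmarkNotFoundError(f"{landmark}: empty candidate set")
    refs = db.entries[landmark]
    if normals is None:
        normals = estimate_normals(cloud.points)
    tree = tree or cKDTree(cloud.points)
    for idx in candidates:
        try:
            desc = compute_fpfh(cloud, int(idx), radius, normals=normals,
                                tree=tree)
        except DescriptorError:
            continue
        best = min(desc.distance(r) for r in refs)
        if best <= db.tau:
            logger.debug("%s matched at index %d (distance %.2f)",
                         landmark, idx, best)
            return int(idx)
    raise LandmarkNotFoundError(
        f"{landmark}: none of {candidates.size} candidates within tau={db.tau}")


def best_feature_point(candidates: np.ndarray, cloud: PointCloud,
                       landmark: str, db: FeatureModelDB, radius: float,
                       normals: np.ndarray | None = None,
                       tree: cKDTree | None = None) -> tuple[int, float]:
    """Candidate with the globally smallest descriptor distance.

    Recovery path for when the first-match rule finds nothing within tau
    (e.g. a locally contaminated neighborhood on this particular scan);
    returns (index, distance) so the caller can log the degradation.
    """
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        raise LandmarkNotFoundError(f"{landmark}: empty candidate set")
    refs = db.entries[landmark]
    if normals is None:
        normals = estimate_normals(cloud.points)
    tree = tree or cKDTree(cloud.points)
    best_idx, best_d = -1, np.inf
    for idx in candidates:
        try:
            desc = compute_fpfh(cloud, int(idx), radius, normals=normals,
                                tree=tree)
        except DescriptorError:
            continue
        d = min(desc.distance(r) for r in refs)
        if d < best_d:
            best_idx, best_d = int(idx), d
    if best_idx < 0:
        raise LandmarkNotFoundError(
            f"{landmark}: no candidate had a computable descriptor")
    return best_idx, float(best_d)
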