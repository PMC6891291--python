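"""Landmark-based body-dimension measurement and the error report.

Six anatomical landmarks are recognized on the normalized body cloud
(withers top, brisket bottom, back top, waist top, and the two body-length
end points). Heights (withers, back, waist) are perpendicular distances
from the upper landmark to the fitted ground plane; chest depth is the
ground-normal distance between the brisket point and the highest back-line
point in a small vertical cylinder above it; body length is the straight
3D distance between its two landmarks. An error report compares automatic
against manual reference values as 100 x |auto - manual| / manual, rounded
half-up to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (AuxiliaryPointError, NotCattleError, ParameterError,
                     PipelineError)
from .errors import LandmarkNotFoundError
from .features import (FeatureModelDB, best_feature_point, build_feature_db,
                       match_feature_point)
from .geometry import (candidate_regions, estimate_normals,
                       length_height_coords, orientation_correct,
                       normalize_pose, principal_curvatures,
                       rules_from_priors, DEFAULT_LANDMARK_RULES)
from .preprocess import FilterParams, preprocess
from .segment import PlaneModel, SegmentParams, extract_subject
from .synth import (DIMENSION_NAMES, LANDMARK_NAMES, SceneConfig,
                    generate_scene)

logger = logging.getLogger(__name__)


#: Reference automatic/manual measurements (meters) for three adult
#: Qinchuan cattle, identified by ear tag. Used as the worked example for
#: the error report.
REFERENCE_MEASUREMENTS = {
    "Q0392": {
        "automatic": {"withers_height": 1.213, "chest_depth": 0.629,
                      "back_height": 1.124, "waist_height": 1.186,
                      "body_length": 1.387},
        "manual": {"withers_height": 1.211, "chest_depth": 0.630,
                   "back_height": 1.110, "waist_height": 1.175,
                   "body_length": 1.355},
    },
    "Q0526": {
        "automatic": {"withers_height": 1.256, "chest_depth": 0.610,
                      "back_height": 1.082, "waist_height": 1.239,
                      "body_length": 1.410},
        "manual": {"withers_height": 1.255, "chest_depth": 0.619,
                   "back_height": 1.095, "waist_height": 1.237,
                   "body_length": 1.414},
    },
    "Q0456": {
        "automatic": {"withers_height": 1.242, "chest_depth": 0.635,
                      "back_height": 1.133, "waist_height": 1.169,
                      "body_length": 1.615},
        "manual": {"withers_height": 1.238, "chest_depth": 0.637,
                   "back_height": 1.134, "waist_height": 1.166,
                   "body_length": 1.612},
    },
}


@dataclass
class BodyDimensions:
    """The five measurements (meters) plus their provenance landmarks."""

    withers_height: float
    chest_depth: float
    back_height: float
    waist_height: float
    body_length: float
    landmarks: dict = field(default_factory=dict)
    auxiliary: dict = field(default_factory=dict)
    ground_y: float = 0.0

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in DIMENSION_NAMES}


@dataclass
class ErrorReport:
    """Per-dimension automatic vs manual comparison."""

    rows: dict  # dimension -> {"automatic", "manual", "error_percent"}

    @property
    def mean_error_percent(self) -> float:
        return float(np.mean([r["error_percent"] for r in self.rows.values()]))


def error_percent(automatic: float, manual: float) -> float:
    """100 |auto - manual| / manual, rounded half-up to 2 decimals."""
    if manual <= 0:
        raise ParameterError("manual reference value must be > 0")
    raw = Decimal(100) * abs(Decimal(repr(automatic)) - Decimal(repr(manual))) \
        / Decimal(repr(manual))
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def error_report(automatic: "BodyDimensions | dict", manual: dict) -> ErrorReport:
    """Compare automatic measurements against manual references."""
    auto = automatic.as_dict() if isinstance(automatic, BodyDimensions) \
        else dict(automatic)
    rows = {}
    for name in DIMENSION_NAMES:
        if name not in auto or name not in manual:
            raise ParameterError(f"both measurement sets must contain {name!r}")
        rows[name] = {
            "automatic": float(auto[name]),
            "manual": float(manual[name]),
            "error_percent": error_percent(auto[name], manual[name]),
        }
    return ErrorReport(rows=rows)


# ---------------------------------------------------------------------------
# auxiliary points and dimensions
# ---------------------------------------------------------------------------

def derive_auxiliary_points(landmarks: dict, ground: PlaneModel,
                            cloud: PointCloud,
                            chest_cylinder_radius: float = 0.03) -> dict:
    """Construct the non-recognized helper points.

    For each upper height landmark the lower point is its foot of
    perpendicular on the ground plane. The chest *upper* point is the cloud
    point with the greatest ground distance inside a thin vertical cylinder
    (radius ``chest_cylinder_radius``) through the chest lower point.
    """
    n = ground.normal
    aux = {}
    for name in ("withers_upper", "back_upper", "waist_upper"):
        p = np.asarray(landmarks[name])
        aux[name.replace("_upper", "_lower")] = p - ground.distance(p[None])[0] * n
    c = np.asarray(landmarks["chest_lower"])
    rel = cloud.points - c
    horiz = rel - np.outer(rel @ n, n)
    in_cyl = np.linalg.norm(horiz, axis=1) <= chest_cylinder_radius
    if not in_cyl.any():
        raise AuxiliaryPointError(
            f"no cloud point within {chest_cylinder_radius} m of the chest axis")
    heights = ground.distance(cloud.points[in_cyl])
    aux["chest_upper"] = cloud.points[in_cyl][np.argmax(heights)]
    return aux


def compute_dimensions(landmarks: dict, auxiliary: dict, ground: PlaneModel
                       ) -> BodyDimensions:
    """The five body dimensions from landmarks + auxiliary points."""
    n = ground.normal

    def h(p):
        return float(abs(ground.distance(np.asarray(p)[None])[0]))

    chest = float((np.asarray(auxiliary["chest_upper"])
                   - np.asarray(landmarks["chest_lower"])) @ n)
    body_len = float(np.linalg.norm(np.asarray(landmarks["bodylen_upper"])
                                    - np.asarray(landmarks["bodylen_lower"])))
    return BodyDimensions(
        withers_height=h(landmarks["withers_upper"]),
        chest_depth=abs(chest),
        back_height=h(landmarks["back_upper"]),
        waist_height=h(landmarks["waist_upper"]),
        body_length=body_len,
        landmarks={k: np.asarray(v) for k, v in landmarks.items()},
        auxiliary={k: np.asarray(v) for k, v in auxiliary.items()},
        ground_y=-float(ground.offset),
    )


#: How each landmark sits on its feature surface: the recognized match is
#: refined to the local extremum — the crest points are height maxima, the
#: brisket a height minimum, and the body-length end points protrude
#: forward (-x) / backward (+x) from the trunk.
_REFINE_MODE = {
    "withers_upper": "max_height",   # a true local height maximum
    "back_upper": "crest",           # highest point at this length station
    "waist_upper": "crest",          # (ball-max would drift uphill along
    "chest_lower": "min_height",     # the sloping back line)
    "bodylen_upper": "apex",         # bump apex = local k1 maximum
    "bodylen_lower": "apex",
}


def _refine_landmark(name: str, index: int, normalized: PointCloud,
                     subject: PointCloud, ground: PlaneModel,
                     radius: float, curvature=None) -> int:
    """Snap a matched landmark to the center of its feature surface.

    First-match recognition lands somewhere on the candidate patch; the
    measurement point is the patch's defining extremum within *radius* of
    the match.
    """
    if radius <= 0:
        return index
    mode = _REFINE_MODE.get(name)
    if mode is None:
        return index
    d = np.linalg.norm(normalized.points - normalized.points[index], axis=1)
    if mode == "crest":
        slab = np.abs(normalized.points[:, 0]
                      - normalized.points[index, 0]) <= 0.4 * radius
        local = np.nonzero(slab & (d <= radius))[0]
        h = ground.distance(subject.points[local])
        return int(local[np.argmax(h)])
    local = np.nonzero(d <= radius)[0]
    if mode in ("max_height", "min_height"):
        h = ground.distance(subject.points[local])
        pick = np.argmax(h) if mode == "max_height" else np.argmin(h)
        return int(local[pick])
    # bump apex: the local maximum of the larger principal curvature
    if curvature is None:
        return index
    k1 = np.where(curvature.valid[local], curvature.k1[local], -np.inf)
    if not np.isfinite(k1).any():
        return index
    return int(local[np.argmax(k1)])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class MeasureConfig:
    """All stage parameters of the measurement pipeline."""

    filters: FilterParams = field(default_factory=FilterParams)
    segmentation: SegmentParams = field(default_factory=SegmentParams)
    curvature_knn: int = 16
    fpfh_radius: float = 0.10
    chest_cylinder_radius: float = 0.05
    prior_band_dt: float = 0.04
    prior_band_du: float = 0.08
    prior_band_dz: float = 0.05
    refine_radius: float = 0.05
    landmark_rules: dict | None = None
    use_classifier_gate: bool = False
    seed: int = 0


@dataclass
class MeasureResult:
    dimensions: BodyDimensions
    report: ErrorReport | None
    subject: PointCloud
    normalized: PointCloud
    ground: PlaneModel
    mirrored: bool


def measure_pipeline(scene: PointCloud, db: FeatureModelDB,
                     config: MeasureConfig | None = None,
                     classifier=None, manual: dict | None = None
                     ) -> MeasureResult:
    """Run the full chain from a raw scene to the five dimensions.

    preprocess -> subject extraction -> (optional classifier gate) -> pose
    normalization -> orientation correction -> curvature typing ->
    candidate regions -> first-match landmark recognition -> auxiliary
    points -> dimensions. With *manual* reference values an error report is
    attached. Stage failures surface as :class:`PipelineError` carrying the
    stage name.
    """
    cfg = config or MeasureConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            if isinstance(exc, (PipelineError, NotCattleError)):
                raise
            raise PipelineError(name, str(exc)) from exc

    filtered = stage("preprocess", lambda: preprocess(scene, cfg.filters))
    subject, ground = stage("segment", lambda: extract_subject(
        filtered, cfg.segmentation, seed=cfg.seed))
    centroid = subject.points.mean(axis=0)
    ground = ground.oriented_towards(centroid)

    if cfg.use_classifier_gate:
        if classifier is None:
            raise PipelineError("classify", "gate enabled but no classifier given")
        from .transfer import classify as _classify
        label, score = _classify(classifier, subject, seed=cfg.seed)
        logger.info("classifier gate: %r (score %.3f)", label, score)
        if label not in ("cattle", 1):
            raise NotCattleError(f"subject classified as {label!r} "
                                 f"(score {score:.3f})")

    normalized, frame = stage("normalize", lambda: normalize_pose(
        subject, up_hint=ground.normal))
    normalized, mirrored = stage("orient", lambda: orientation_correct(normalized))

    curv = stage("curvature", lambda: principal_curvatures(
        normalized, knn_k=cfg.curvature_knn))
    rules = cfg.landmark_rules
    wide_rules = None
    if rules is None and db.landmark_priors:
        rules = rules_from_priors(db.landmark_priors, dt=cfg.prior_band_dt,
                                  du=cfg.prior_band_du, dz=cfg.prior_band_dz)
        wide_rules = rules_from_priors(db.landmark_priors,
                                       dt=2 * cfg.prior_band_dt,
                                       du=2 * cfg.prior_band_du,
                                       dz=2 * cfg.prior_band_dz)
    cands = stage("candidates", lambda: candidate_regions(
        curv, normalized, rules))
    wide_cands = candidate_regions(curv, normalized, wide_rules) \
        if wide_rules is not None else cands

    tree = cKDTree(normalized.points)
    normals = estimate_normals(normalized.points, tree=tree)

    def _match(name: str) -> int:
        # first-match within tau; on failure widen the candidate band, and
        # as a last resort take the best-scoring candidate (logged — the
        # neighborhood on this scan did not reach reference quality)
        try:
            return match_feature_point(cands[name], normalized, name, db,
                                       cfg.fpfh_radius, normals=normals,
                                       tree=tree)
        except LandmarkNotFoundError:
            pass
        try:
            if wide_cands is not cands:
                return match_feature_point(wide_cands[name], normalized, name,
                                           db, cfg.fpfh_radius,
                                           normals=normals, tree=tree)
        except LandmarkNotFoundError:
            pass
        idx, dist = best_feature_point(wide_cands[name], normalized, name, db,
                                       cfg.fpfh_radius, normals=normals,
                                       tree=tree)
        logger.warning("%s: recognition degraded, best candidate at "
                       "descriptor distance %.1f (tau %.1f)", name, dist, db.tau)
        return idx

    landmarks_norm = {}
    for name in LANDMARK_NAMES:
        landmarks_norm[name] = stage(f"match:{name}", lambda n=name: _match(n))

    landmarks_norm = {k: _refine_landmark(k, v, normalized, subject, ground,
                                          cfg.refine_radius, curvature=curv)
                      for k, v in landmarks_norm.items()}
    # landmark indices are positions in the subject cloud (normalization and
    # mirroring never reorder points), so sensor-frame coordinates are a
    # direct lookup — heights are measured against the sensor-frame plane
    landmarks = {k: subject.points[v] for k, v in landmarks_norm.items()}
    aux = stage("auxiliary", lambda: derive_auxiliary_points(
        landmarks, ground, subject, cfg.chest_cylinder_radius))
    dims = stage("dimensions", lambda: compute_dimensions(landmarks, aux, ground))

    report = error_report(dims, manual) if manual is not None else None
    logger.info("dimensions: %s", {k: round(v, 4) for k, v in dims.as_dict().items()})
    return MeasureResult(dimensions=dims, report=report, subject=subject,
                         normalized=normalized, ground=ground, mirrored=mirrored)


def reference_db_from_scenes(seeds, config: SceneConfig | None = None,
                             measure_cfg: MeasureConfig | None = None,
                             tau: float | None = None,
                             n_refs_per_landmark: int = 4) -> FeatureModelDB:
    """Build a feature database from generated reference animals.

    For each seed a scene is generated, preprocessed, segmented and
    normalized; the true landmark positions are snapped to their nearest
    subject points and those points' descriptors become the references.
    This mirrors the field procedure of recording the database on animals
    measured by hand.
    """
    mcfg = measure_cfg or MeasureConfig()
    examples = []
    tu: dict = {name: [] for name in LANDMARK_NAMES}
    for seed in seeds:
        scene, truth = generate_scene(config, seed=seed)
        filtered = preprocess(scene, mcfg.filters)
        subject, ground = extract_subject(filtered, mcfg.segmentation, seed=seed)
        ground = ground.oriented_towards(subject.points.mean(axis=0))
        normalized, _ = normalize_pose(subject, up_hint=ground.normal)
        normalized, _ = orientation_correct(normalized)
        t, u = length_height_coords(normalized)
        tree = cKDTree(subject.points)
        for name in LANDMARK_NAMES:
            # the snapped point plus its closest neighbors: several
            # descriptors per animal cover the local sampling variation of
            # a small anatomical feature
            _, near = tree.query(truth.landmarks_true[name], k=n_refs_per_landmark)
            for idx in np.atleast_1d(near):
                examples.append((name, normalized, int(idx)))
            idx0 = int(np.atleast_1d(near)[0])
            tu[name].append((t[idx0], u[idx0],
                             abs(normalized.points[idx0, 2])))
    db = build_feature_db(examples, mcfg.fpfh_radius, tau=tau)
    db.landmark_priors = {
        name: (float(np.mean([p[0] for p in pts])),
               float(np.mean([p[1] for p in pts])),
               float(np.std([p[0] for p in pts])),
               float(np.std([p[1] for p in pts])),
               float(np.max([p[2] for p in pts])))
        for name, pts in tu.items()}
    return db
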