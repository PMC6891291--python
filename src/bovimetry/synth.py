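"""Synthetic scene and dataset generation with exact ground truth.

The scene generator emulates a sparse ToF-LiDAR acquisition of a standing
adult beef animal: a parametric body (ellipsoid torso with a raised withers
ridge, a brisket bulge, shoulder and pin-bone bosses, four cylindrical legs
and a head/neck lobe), a ground plane, free-standing background clutter, and
additive Gaussian range noise. All landmark positions and the five body
dimensions are computed *from the generative parameters*, so every generated
scene carries an exact reference measurement.

Canonical body frame before the random scene pose is applied:
x = body-length axis with the head on -x and the tail on +x,
y = height (up, ground at y = 0), z = chest width. The withers ridge sits on
the front half so that the front half's maximum height always exceeds the
rear half's — the property the orientation-correction rule relies on.

The shape-class generator provides a 16-family labeled stand-in for a
generic 3D shape corpus used to pre-train the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .cloud import PointCloud
from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Canonical landmark names, in the order dimensions are reported.
LANDMARK_NAMES = (
    "withers_upper",
    "chest_lower",
    "back_upper",
    "waist_upper",
    "bodylen_upper",
    "bodylen_lower",
)

DIMENSION_NAMES = (
    "withers_height",
    "chest_depth",
    "back_height",
    "waist_height",
    "body_length",
)


@dataclass
class SceneConfig:
    """Generative parameters of a synthetic acquisition scene (meters)."""

    # torso: axis-aligned ellipsoid, semi-axes (length, height, width)
    torso_length: float = 0.85
    torso_height: float = 0.35
    torso_width: float = 0.30
    torso_center_height: float = 0.90

    # withers ridge: Gaussian height ridge on the top of the front half
    withers_x: float = -0.45
    withers_amp: float = 0.10
    withers_sx: float = 0.15
    withers_sz: float = 0.25

    # brisket: Gaussian bulge on the belly behind the forelegs
    brisket_x: float = -0.35
    brisket_amp: float = 0.04
    brisket_sx: float = 0.08
    brisket_sz: float = 0.10

    # shoulder / pin-bone bosses: radial bumps marking the body-length ends
    boss_amp: float = 0.03
    boss_sigma: float = 0.05
    boss_angle_deg: float = 30.0  # elevation of the boss base on the z=0 ellipse

    # head/neck lobe (ellipsoid) and legs (cylinders)
    head_center: tuple = (-1.05, 0.95, 0.0)
    head_semi: tuple = (0.22, 0.16, 0.13)
    leg_radius: float = 0.07
    leg_x: float = 0.55
    leg_z: float = 0.18
    leg_top: float = 0.75

    # sampling / nuisance structure
    # ground density matches the subject's sensor-like spacing (~3 cm)
    n_subject_points: int = 6000
    n_ground_points: int = 12000
    ground_extent_x: float = 2.0
    ground_extent_z: float = 1.5
    n_clutter_objects: int = 3
    clutter_points_each: int = 150
    noise_sigma: float = 0.003

    # random scene pose
    yaw_range_deg: float = 180.0
    tilt_range_deg: float = 3.0
    translation_range: float = 1.0

    def validate(self) -> None:
        for name in ("torso_length", "torso_height", "torso_width",
                     "torso_center_height", "withers_amp", "leg_radius",
                     "n_subject_points", "n_ground_points", "noise_sigma"):
            v = getattr(self, name)
            if name == "noise_sigma":
                if v < 0:
                    raise ConfigError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.withers_amp <= 0:
            raise ConfigError("withers ridge amplitude must be positive "
                              "(the front half must rise above the rear half)")


@dataclass
class SceneGroundTruth:
    """Exact reference values attached to a generated scene.

    ``landmarks_true`` and ``ground_plane`` are expressed in the scene
    (sensor) frame, i.e. after the random pose was applied. ``labels`` marks
    the provenance of every point in the returned cloud in stored order:
    0 = subject, 1 = ground, 2 = clutter.
    """

    dimensions_true: dict
    landmarks_true: dict
    ground_plane: tuple  # (unit normal, offset): n·p + offset = 0
    seed: int
    labels: np.ndarray = field(default=None, repr=False)
    sampling_step: float = 0.0


@dataclass
class LabeledCloudSet:
    """Clouds with integer class labels and class names."""

    clouds: list
    labels: list
    class_names: list

    def __post_init__(self) -> None:
        if len(self.clouds) != len(self.labels):
            raise ConfigError("clouds and labels must have equal length")
        for lbl in self.labels:
            if not 0 <= int(lbl) < len(self.class_names):
                raise ConfigError(f"label {lbl} outside [0, {len(self.class_names)})")

    def __len__(self) -> int:
        return len(self.clouds)


# ---------------------------------------------------------------------------
# parametric body surface
# ---------------------------------------------------------------------------

def _ridge(x, z, cx, amp, sx, sz):
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    return amp * np.exp(-((x - cx) ** 2 / (2 * sx ** 2) + z ** 2 / (2 * sz ** 2)))


def _shell(cfg: SceneConfig, x, z):
    """sqrt(1 - (x/a)^2 - (z/c)^2), clipped at 0 — the torso half-height factor."""
    a, c = cfg.torso_length, cfg.torso_width
    return np.sqrt(np.clip(1.0 - (np.asarray(x) / a) ** 2 - (np.asarray(z) / c) ** 2,
                           0.0, None))


def top_height(cfg: SceneConfig, x, z):
    """Height of the back line at (x, z), ground at 0 (bosses excluded)."""
    s = _shell(cfg, x, z)
    bump = _ridge(x, z, cfg.withers_x, cfg.withers_amp, cfg.withers_sx, cfg.withers_sz)
    return cfg.torso_center_height + s * (cfg.torso_height + bump)


def belly_height(cfg: SceneConfig, x, z):
    """Height of the belly line at (x, z) (bosses excluded)."""
    s = _shell(cfg, x, z)
    bump = _ridge(x, z, cfg.brisket_x, cfg.brisket_amp, cfg.brisket_sx, cfg.brisket_sz)
    return cfg.torso_center_height - s * (cfg.torso_height + bump)


def _boss_bases(cfg: SceneConfig):
    """Undisplaced (on-ellipsoid) base points of the shoulder / pin bosses."""
    a, b, yc = cfg.torso_length, cfg.torso_height, cfg.torso_center_height
    th = np.deg2rad(cfg.boss_angle_deg)
    rear = np.array([a * np.cos(th), yc + b * np.sin(th), 0.0])
    front = np.array([-a * np.cos(th), yc + b * np.sin(th), 0.0])
    return front, rear


def _ellipsoid_normal(cfg: SceneConfig, p0: np.ndarray) -> np.ndarray:
    a, b, c = cfg.torso_length, cfg.torso_height, cfg.torso_width
    yc = cfg.torso_center_height
    g = np.stack([p0[..., 0] / a ** 2,
                  (p0[..., 1] - yc) / b ** 2,
                  p0[..., 2] / c ** 2], axis=-1)
    return g / np.linalg.norm(g, axis=-1, keepdims=True)


def _displace(cfg: SceneConfig, p0: np.ndarray, uy: np.ndarray) -> np.ndarray:
    """Map undisplaced torso-ellipsoid samples through the bump fields.

    ``uy`` is the unit-sphere y component of each sample: the ridge/bulge
    displacement tapers as max(+-uy, 0), which makes the column-top heights
    agree exactly with :func:`top_height` / :func:`belly_height`.
    """
    p = p0.copy()
    x, z = p0[:, 0], p0[:, 2]
    wd = _ridge(x, z, cfg.withers_x, cfg.withers_amp, cfg.withers_sx, cfg.withers_sz)
    bd = _ridge(x, z, cfg.brisket_x, cfg.brisket_amp, cfg.brisket_sx, cfg.brisket_sz)
    p[:, 1] += wd * np.clip(uy, 0.0, None)
    p[:, 1] -= bd * np.clip(-uy, 0.0, None)
    for base in _boss_bases(cfg):
        d = np.linalg.norm(p0 - base, axis=1)
        near = d < 3.0 * cfg.boss_sigma
        if np.any(near):
            amp = cfg.boss_amp * np.exp(-d[near] ** 2 / (2 * cfg.boss_sigma ** 2))
            p[near] += amp[:, None] * _ellipsoid_normal(cfg, p0[near])
    return p


def _boss_apex(cfg: SceneConfig, base: np.ndarray) -> np.ndarray:
    """Exact displaced position of a boss base point (apex of the boss)."""
    yc, b = cfg.torso_center_height, cfg.torso_height
    uy = (base[1] - yc) / b
    p = _displace(cfg, base[None, :], np.array([uy]))
    return p[0]


def _sample_ellipsoid(rng, n, semi, center):
    """Area-uniform surface samples of an axis-aligned ellipsoid (rejection)."""
    a, b, c = semi
    out = np.empty((0, 3))
    mu_max = max(b * c, a * c, a * b)
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 256)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        mu = np.sqrt((b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2
                     + (a * b * u[:, 2]) ** 2)
        keep = rng.uniform(0, mu_max, size=m) < mu
        pts = u[keep] * np.array(semi)
        out = np.vstack([out, pts])
    out = out[:n]
    return out + np.asarray(center), out  # displaced later needs unit components


def sample_body(cfg: SceneConfig, rng: np.random.Generator,
                n_points: int | None = None) -> np.ndarray:
    """Noise-free samples of the full body surface in the canonical frame."""
    n = cfg.n_subject_points if n_points is None else n_points
    n_torso = int(round(n * 0.62))
    n_head = int(round(n * 0.14))
    n_leg = (n - n_torso - n_head) // 4
    n_torso = n - n_head - 4 * n_leg  # absorb rounding

    semi = (cfg.torso_length, cfg.torso_height, cfg.torso_width)
    center = (0.0, cfg.torso_center_height, 0.0)
    pts, raw = _sample_ellipsoid(rng, n_torso, semi, center)
    uy = raw[:, 1] / cfg.torso_height
    torso = _displace(cfg, pts, uy)

    head, _ = _sample_ellipsoid(rng, n_head, cfg.head_semi, cfg.head_center)

    legs = []
    for sx in (-1.0, 1.0):
        for sz in (-1.0, 1.0):
            th = rng.uniform(0, 2 * np.pi, n_leg)
            h = rng.uniform(0.0, cfg.leg_top, n_leg)
            legs.append(np.column_stack([
                sx * cfg.leg_x + cfg.leg_radius * np.cos(th),
                h,
                sz * cfg.leg_z + cfg.leg_radius * np.sin(th),
            ]))
    return np.vstack([torso, head] + legs)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _true_landmarks(cfg: SceneConfig) -> dict:
    """Landmark positions in the canonical frame, from the generative model."""
    a = cfg.torso_length
    res = minimize_scalar(lambda x: -top_height(cfg, x, 0.0),
                          bounds=(cfg.withers_x - 2 * cfg.withers_sx, -0.05 * a),
                          method="bounded", options={"xatol": 1e-10})
    x_w = float(res.x)
    res = minimize_scalar(lambda x: belly_height(cfg, x, 0.0),
                          bounds=(cfg.brisket_x - 2 * cfg.brisket_sx,
                                  cfg.brisket_x + 2 * cfg.brisket_sx),
                          method="bounded", options={"xatol": 1e-10})
    x_c = float(res.x)
    front, rear = _boss_bases(cfg)
    lm = {
        "withers_upper": np.array([x_w, float(top_height(cfg, x_w, 0.0)), 0.0]),
        "chest_lower": np.array([x_c, float(belly_height(cfg, x_c, 0.0)), 0.0]),
        "back_upper": np.array([0.0, float(top_height(cfg, 0.0, 0.0)), 0.0]),
        "waist_upper": np.array([0.40 / 0.85 * a,
                                 float(top_height(cfg, 0.40 / 0.85 * a, 0.0)), 0.0]),
        "bodylen_upper": _boss_apex(cfg, front),
        "bodylen_lower": _boss_apex(cfg, rear),
    }
    return lm


def _true_dimensions(cfg: SceneConfig, lm: dict) -> dict:
    chest_top = float(top_height(cfg, lm["chest_lower"][0], 0.0))
    return {
        "withers_height": float(lm["withers_upper"][1]),
        "chest_depth": chest_top - float(lm["chest_lower"][1]),
        "back_height": float(lm["back_upper"][1]),
        "waist_height": float(lm["waist_upper"][1]),
        "body_length": float(np.linalg.norm(lm["bodylen_upper"] - lm["bodylen_lower"])),
    }


def _clutter(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Free-standing blobs resting on the ground, clear of the subject."""
    pts = []
    # subject axis-aligned bounding box in the canonical frame, with margin
    x_lo = cfg.head_center[0] - cfg.head_semi[0] - 0.6
    x_hi = cfg.torso_length + 0.6
    z_hi = cfg.torso_width + 0.6
    for _ in range(cfg.n_clutter_objects):
        size = rng.uniform(0.10, 0.25)
        for _ in range(200):
            cx = rng.uniform(-cfg.ground_extent_x + size, cfg.ground_extent_x - size)
            cz = rng.uniform(-cfg.ground_extent_z + size, cfg.ground_extent_z - size)
            if not (x_lo < cx < x_hi and -z_hi < cz < z_hi):
                break
        center = np.array([cx, size, cz])
        if rng.uniform() < 0.5:  # sphere surface
            u = rng.normal(size=(cfg.clutter_points_each, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts.append(center + size * u)
        else:  # box surface
            p = rng.uniform(-size, size, size=(cfg.clutter_points_each, 3))
            ax = rng.integers(0, 3, cfg.clutter_points_each)
            sgn = rng.choice([-1.0, 1.0], cfg.clutter_points_each)
            p[np.arange(len(p)), ax] = sgn * size
            pts.append(center + p)
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_scene(config: SceneConfig | None = None, seed: int = 0,
                   ) -> tuple[PointCloud, SceneGroundTruth]:
    """Generate one acquisition scene plus its exact ground truth.

    The returned cloud concatenates subject, ground and clutter points (in
    that order; see ``SceneGroundTruth.labels``), perturbed by isotropic
    Gaussian noise and moved through a random rigid scene pose (yaw about the
    vertical, small tilt, horizontal translation). Identical ``(config,
    seed)`` always produce identical output.
    """
    cfg = config or SceneConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    subject = sample_body(cfg, rng)
    gx, gz = cfg.ground_extent_x, cfg.ground_extent_z
    ground = np.column_stack([
        rng.uniform(-gx, gx, cfg.n_ground_points),
        np.zeros(cfg.n_ground_points),
        rng.uniform(-gz, gz, cfg.n_ground_points),
    ])
    clutter = _clutter(cfg, rng)

    pts = np.vstack([subject, ground, clutter])
    labels = np.concatenate([
        np.zeros(len(subject), dtype=np.int8),
        np.ones(len(ground), dtype=np.int8),
        np.full(len(clutter), 2, dtype=np.int8),
    ])
    if cfg.noise_sigma > 0:
        pts = pts + rng.normal(scale=cfg.noise_sigma, size=pts.shape)

    yaw = rng.uniform(-np.deg2rad(cfg.yaw_range_deg), np.deg2rad(cfg.yaw_range_deg))
    tilt = np.deg2rad(cfg.tilt_range_deg)
    rot = _rot_y(yaw) @ _rot_x(rng.uniform(-tilt, tilt)) @ _rot_z(rng.uniform(-tilt, tilt))
    trans = np.array([rng.uniform(-cfg.translation_range, cfg.translation_range),
                      0.0,
                      rng.uniform(-cfg.translation_range, cfg.translation_range)])
    pts = pts @ rot.T + trans

    lm = _true_landmarks(cfg)
    dims = _true_dimensions(cfg, lm)
    lm_scene = {k: rot @ v + trans for k, v in lm.items()}
    normal = rot @ np.array([0.0, 1.0, 0.0])
    offset = -float(normal @ trans)

    # mean surface sample spacing on the torso (area / n, as a length scale)
    area = 4 * np.pi * ((cfg.torso_length * cfg.torso_height) ** 1.6 / 3
                        + (cfg.torso_length * cfg.torso_width) ** 1.6 / 3
                        + (cfg.torso_height * cfg.torso_width) ** 1.6 / 3) ** (1 / 1.6)
    step = float(np.sqrt(area / (0.62 * cfg.n_subject_points)))

    truth = SceneGroundTruth(
        dimensions_true=dims,
        landmarks_true=lm_scene,
        ground_plane=(normal, offset),
        seed=seed,
        labels=labels,
        sampling_step=step,
    )
    logger.info("scene seed=%d: %d subject, %d ground, %d clutter points",
                seed, len(subject), len(ground), len(clutter))
    return PointCloud(pts), truth


def generate_silhouettes(n: int, n_points: int, seed: int,
                         scale_jitter: float = 0.1) -> list:
    """Subject-only body clouds (no ground/clutter) for classifier training.

    Each cloud is centered, randomly yawed, uniformly scaled within
    ``1 +- scale_jitter`` and lightly noised — the shape of a segmented
    silhouette as it reaches the classifier.
    """
    rng = np.random.default_rng(seed)
    cfg = SceneConfig()
    out = []
    for _ in range(n):
        pts = sample_body(cfg, rng, n_points=n_points)
        pts = pts - pts.mean(axis=0)
        scale = rng.uniform(1 - scale_jitter, 1 + scale_jitter)
        pts = scale * pts @ _rot_y(rng.uniform(0, 2 * np.pi)).T
        pts += rng.normal(scale=cfg.noise_sigma, size=pts.shape)
        out.append(PointCloud(pts))
    return out


# ---------------------------------------------------------------------------
# labeled shape-class dataset (classifier pre-training stand-in)
# ---------------------------------------------------------------------------

def _fam_plane(rng, n):
    p = rng.uniform(-1, 1, (n, 3))
    p[:, 2] = 0.0
    return p


def _fam_sphere(rng, n):
    u = rng.normal(size=(n, 3))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _fam_cylinder(rng, n):
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([np.cos(th), np.sin(th), rng.uniform(-1, 1, n)])


def _fam_box(rng, n):
    p = rng.uniform(-1, 1, (n, 3))
    ax = rng.integers(0, 3, n)
    p[np.arange(n), ax] = rng.choice([-1.0, 1.0], n)
    return p


def _fam_saddle(rng, n):
    xy = rng.uniform(-1, 1, (n, 2))
    return np.column_stack([xy, xy[:, 0] ** 2 - xy[:, 1] ** 2])


def _fam_torus(rng, n):
    u, v = rng.uniform(0, 2 * np.pi, n), rng.uniform(0, 2 * np.pi, n)
    r, R = 0.3, 1.0
    return np.column_stack([(R + r * np.cos(v)) * np.cos(u),
                            (R + r * np.cos(v)) * np.sin(u),
                            r * np.sin(v)])


def _fam_two_lobe(rng, n):
    s = _fam_sphere(rng, n) * 0.5
    side = rng.choice([-0.7, 0.7], n)
    s[:, 0] += side
    return s


def _fam_ellipsoid(rng, n):
    return _fam_sphere(rng, n) * np.array([1.6, 0.5, 0.35])


def _fam_cone(rng, n):
    h = rng.uniform(0, 1, n)
    th = rng.uniform(0, 2 * np.pi, n)
    r = 1 - h
    return np.column_stack([r * np.cos(th), r * np.sin(th), h])


def _fam_paraboloid(rng, n):
    xy = rng.uniform(-1, 1, (n, 2))
    return np.column_stack([xy, xy[:, 0] ** 2 + xy[:, 1] ** 2])


def _fam_bowl(rng, n):
    u = _fam_sphere(rng, n)
    u[:, 2] = -np.abs(u[:, 2])
    return u


def _fam_annulus(rng, n):
    th = rng.uniform(0, 2 * np.pi, n)
    r = rng.uniform(0.5, 1.0, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])


def _fam_helix(rng, n):
    t = rng.uniform(0, 4 * np.pi, n)
    jig = rng.normal(scale=0.08, size=(n, 3))
    return np.column_stack([np.cos(t), np.sin(t), t / (4 * np.pi) * 2 - 1]) + jig


def _fam_cross(rng, n):
    p = rng.uniform(-1, 1, (n, 3))
    which = rng.integers(0, 2, n)
    p[which == 0, 1] *= 0.2
    p[which == 0, 2] *= 0.2
    p[which == 1, 0] *= 0.2
    p[which == 1, 2] *= 0.2
    return p


def _fam_wedge(rng, n):
    p = rng.uniform(-1, 1, (n, 3))
    p[:, 2] = (p[:, 0] + 1) / 2 * p[:, 2]
    return p


def _fam_stairs(rng, n):
    x = rng.uniform(-1, 1, n)
    z = np.floor((x + 1) * 2) / 2 - 0.75
    return np.column_stack([x, rng.uniform(-1, 1, n), z])


# (name, sampler, characteristic metric scale in meters): real object
# classes carry class-correlated sizes, and the classifier works in metric
# coordinates, so each family gets a typical size the way a real corpus
# would (vehicle-sized planes, hand-sized cups, ...)
_SHAPE_FAMILIES = [
    ("plane", _fam_plane, 1.8), ("sphere", _fam_sphere, 0.4),
    ("cylinder", _fam_cylinder, 0.9), ("box", _fam_box, 0.7),
    ("saddle", _fam_saddle, 1.0), ("torus", _fam_torus, 0.8),
    ("two_lobe", _fam_two_lobe, 0.5), ("ellipsoid", _fam_ellipsoid, 2.2),
    ("cone", _fam_cone, 0.6), ("paraboloid", _fam_paraboloid, 1.1),
    ("bowl", _fam_bowl, 0.35), ("annulus", _fam_annulus, 0.9),
    ("helix", _fam_helix, 1.3), ("cross", _fam_cross, 1.5),
    ("wedge", _fam_wedge, 1.0), ("stairs", _fam_stairs, 1.6),
]


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_shape_dataset(n_classes: int, per_class: int, n_points: int,
                           seed: int) -> LabeledCloudSet:
    """Labeled clouds drawn from distinct parametric shape families.

    Each cloud gets a random yaw (the corpus this emulates is
    gravity-aligned, as are pose-normalized silhouettes, so orientation
    varies freely only about the vertical), a small tilt jitter, a uniform
    scale jitter in [0.8, 1.2] and 1% additive noise; ``n_points`` must be
    a power of two so the clouds slot directly into a balanced spatial
    tree.
    """
    if n_classes < 2:
        raise ConfigError("need at least 2 classes")
    if n_classes > len(_SHAPE_FAMILIES):
        raise ConfigError(f"at most {len(_SHAPE_FAMILIES)} shape families available")
    if n_points < 1 or (n_points & (n_points - 1)) != 0:
        raise ConfigError(f"n_points must be a power of two, got {n_points}")
    rng = np.random.default_rng(seed)
    clouds, labels = [], []
    for ci in range(n_classes):
        _, fam, size = _SHAPE_FAMILIES[ci]
        for _ in range(per_class):
            p = fam(rng, n_points)
            p = p - p.mean(axis=0)
            rot = (_rot_z(rng.uniform(0, 2 * np.pi))
                   @ _rot_x(rng.normal(scale=np.deg2rad(5)))
                   @ _rot_y(rng.normal(scale=np.deg2rad(5))))
            p = size * rng.uniform(0.8, 1.2) * p @ rot.T
            p += rng.normal(scale=0.01, size=p.shape)
            clouds.append(PointCloud(p))
            labels.append(ci)
    names = [name for name, _, _ in _SHAPE_FAMILIES[:n_classes]]
    return LabeledCloudSet(clouds=clouds, labels=labels, class_names=names)


def make_transfer_dataset(n_cattle: int, n_distractor: int, n_points: int,
                          seed: int) -> LabeledCloudSet:
    """Binary cattle/other dataset for the transfer experiment.

    Class 1 = "cattle" (pose-jittered body silhouettes). Class 0 = "other"
    emulates the non-animal clusters that subject segmentation can hand to
    the classifier gate in practice: ground patches (plane), clutter blobs
    (sphere, box) and post/trough-like objects (cylinder). Every cloud is
    centered and scaled to unit radius by the classifier's own
    canonicalization at training time, so absolute size is not the
    discriminating cue.
    """
    rng = np.random.default_rng(seed)
    cattle = generate_silhouettes(n_cattle, n_points, int(rng.integers(2 ** 31)))
    n_fam = 4  # plane, sphere, cylinder, box: the clutter/ground morphology
    per = int(np.ceil(n_distractor / n_fam))
    shapes = generate_shape_dataset(n_fam, per, n_points, int(rng.integers(2 ** 31)))
    order = rng.permutation(len(shapes.clouds))[:n_distractor]
    clouds = [shapes.clouds[i] for i in order] + cattle
    labels = [0] * n_distractor + [1] * n_cattle
    return LabeledCloudSet(clouds=clouds, labels=labels,
                           class_names=["other", "cattle"])
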