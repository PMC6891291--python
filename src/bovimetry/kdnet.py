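"""A Kd-tree-indexed point-cloud classifier.

A cloud is resampled to exactly 2^depth points and indexed by a perfectly
balanced Kd-tree (recursive median split on the widest-range axis). The
network then computes a representation for every tree node bottom-up: each
leaf's representation is its point's coordinates, and each internal node
applies an affine map — selected by the node's *level* and *split axis* and
shared across all nodes of that level/axis — to the concatenation of its
children's representations, followed by a ReLU. A final affine layer maps
the root representation to class scores. Because the tree canonicalizes the
computation order, classification is invariant to the input point ordering.

Training is plain stochastic gradient descent on the softmax cross-entropy,
with trees rebuilt from fresh seeds every epoch so the model does not
overfit one particular spatial indexing. Gradients are computed in closed
form (the network is a tree of affine+ReLU maps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .errors import ParameterError, TrainingError
from .synth import LabeledCloudSet

logger = logging.getLogger(__name__)


def relu(x):
    """max(0, x), elementwise."""
    return np.maximum(0, x)


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

@dataclass
class KdTreeIndex:
    """Balanced binary split structure over exactly 2^depth points.

    ``split_dims``/``split_values`` are heap-ordered (root at 0, node i's
    children at 2i+1, 2i+2). ``leaf_order`` permutes the resampled points
    into leaf order; ``points`` holds the resampled coordinates.
    """

    depth: int
    split_dims: np.ndarray
    split_values: np.ndarray
    leaf_order: np.ndarray
    points: np.ndarray

    @property
    def n_points(self) -> int:
        return 2 ** self.depth

    def level_axes(self, merge_level: int) -> np.ndarray:
        """Split axes of the parents merged at the given level (0 = leaves'
        first merge, depth-1 = root), left-to-right."""
        tree_level = self.depth - 1 - merge_level
        start = 2 ** tree_level - 1
        return self.split_dims[start:start + 2 ** tree_level]


def _resample(points: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Canonicalize order, then resample to exactly m points.

    Lexicographic sorting first makes the result independent of the input
    point ordering, which is what gives the classifier its permutation
    invariance under a fixed seed.
    """
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    pts = points[order]
    n = len(pts)
    if n == m:
        return pts
    if n > m:
        idx = rng.choice(n, size=m, replace=False)
    else:
        idx = rng.choice(n, size=m, replace=True)
    return pts[np.sort(idx)]


def build_kdtree(cloud: PointCloud, depth: int, seed: int = 0) -> KdTreeIndex:
    """Recursive median split on the widest-range axis.

    The cloud is first resampled (without replacement if large enough, with
    replacement otherwise) to 2^depth points; the seed governs the
    resampling. Median ties are broken by a stable lexicographic sort, so
    the tree is fully deterministic under (cloud, depth, seed).
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    m = 2 ** depth
    rng = np.random.default_rng(seed)
    pts = _resample(cloud.points, m, rng)

    n_internal = m - 1
    split_dims = np.zeros(n_internal, dtype=np.int64)
    split_values = np.zeros(n_internal)
    perm = np.arange(m)

    def split(node: int, lo: int, hi: int) -> None:
        if hi - lo <= 1:
            return
        seg = pts[perm[lo:hi]]
        ranges = seg.max(axis=0) - seg.min(axis=0)
        axis = int(np.argmax(ranges))
        keys = pts[perm[lo:hi]]
        order = np.lexsort((keys[:, (axis + 2) % 3], keys[:, (axis + 1) % 3],
                            keys[:, axis]))
        perm[lo:hi] = perm[lo:hi][order]
        mid = (lo + hi) // 2
        split_dims[node] = axis
        split_values[node] = 0.5 * (pts[perm[mid - 1], axis] + pts[perm[mid], axis])
        split(2 * node + 1, lo, mid)
        split(2 * node + 2, mid, hi)

    split(0, 0, m)
    return KdTreeIndex(depth=depth, split_dims=split_dims,
                       split_values=split_values, leaf_order=perm, points=pts)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 1000
    learning_rate: float = 0.003
    batch_size: int = 4
    seed: int = 0
    holdout_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")


def _level_widths(depth: int, base: int, cap: int) -> list[int]:
    return [min(base * 2 ** i, cap) for i in range(depth)]


@dataclass
class KdNetModel:
    """Level-wise shared-weight tree network plus a fully connected head.

    ``level_params[l]`` is a dict with ``W`` of shape (3, w_out, 2*w_in) and
    ``b`` of shape (3, w_out): one affine map per split axis, shared by all
    nodes of level l. ``fc`` maps the root representation to n_classes
    scores. ``frozen`` marks the level parameters non-trainable (used after
    transfer rewiring).
    """

    depth: int
    n_classes: int
    level_params: list = field(default_factory=list)
    fc: dict = field(default_factory=dict)
    class_names: list | None = None
    frozen: bool = False
    width_base: int = 8
    width_cap: int = 64

    @classmethod
    def initialize(cls, depth: int, n_classes: int, seed: int = 0,
                   class_names: list | None = None, width_base: int = 8,
                   width_cap: int = 64) -> "KdNetModel":
        rng = np.random.default_rng(seed)
        widths = _level_widths(depth, width_base, width_cap)
        params = []
        w_in = 3
        for w_out in widths:
            scale = np.sqrt(2.0 / (2 * w_in))
            params.append({
                "W": rng.normal(scale=scale, size=(3, w_out, 2 * w_in)),
                "b": np.zeros((3, w_out)),
            })
            w_in = w_out
        fc = {"W": rng.normal(scale=np.sqrt(1.0 / w_in), size=(n_classes, w_in)),
              "b": np.zeros(n_classes)}
        return cls(depth=depth, n_classes=n_classes, level_params=params,
                   fc=fc, class_names=class_names,
                   width_base=width_base, width_cap=width_cap)

    def copy(self) -> "KdNetModel":
        return KdNetModel(
            depth=self.depth, n_classes=self.n_classes,
            level_params=[{"W": p["W"].copy(), "b": p["b"].copy()}
                          for p in self.level_params],
            fc={"W": self.fc["W"].copy(), "b": self.fc["b"].copy()},
            class_names=None if self.class_names is None else list(self.class_names),
            frozen=self.frozen, width_base=self.width_base,
            width_cap=self.width_cap)

    def save(self, path: str) -> str:
        arrays = {}
        for i, p in enumerate(self.level_params):
            arrays[f"level{i}_W"] = p["W"]
            arrays[f"level{i}_b"] = p["b"]
        arrays["fc_W"] = self.fc["W"]
        arrays["fc_b"] = self.fc["b"]
        manifest = {"depth": self.depth, "n_classes": self.n_classes,
                    "class_names": self.class_names, "frozen": self.frozen,
                    "width_base": self.width_base, "width_cap": self.width_cap}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str) -> "KdNetModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = [{"W": data[f"level{i}_W"], "b": data[f"level{i}_b"]}
                      for i in range(meta["depth"])]
            fc = {"W": data["fc_W"], "b": data["fc_b"]}
        return cls(depth=meta["depth"], n_classes=meta["n_classes"],
                   level_params=params, fc=fc, class_names=meta["class_names"],
                   frozen=meta["frozen"], width_base=meta["width_base"],
                   width_cap=meta["width_cap"])


def _canonicalize(points: np.ndarray) -> np.ndarray:
    """Center the cloud; metric scale is kept.

    Absolute size is genuine signal for the tasks this classifier serves
    (a body cloud spans meters, clutter decimeters), so only translation is
    removed.
    """
    return points - points.mean(axis=0)


def _forward_cached(model: KdNetModel, leaf_pts: np.ndarray,
                    axes_per_level: list) -> tuple[np.ndarray, list]:
    """Batched bottom-up pass; returns (scores, cache) for backprop.

    ``leaf_pts``: (B, 2^depth, 3) leaf representations in leaf order.
    ``axes_per_level[l]``: (B, n_parents) split axes at merge level l.
    """
    reps = leaf_pts
    cache = []
    for lvl, p in enumerate(model.level_params):
        B, n, w_in = reps.shape
        cc = reps.reshape(B, n // 2, 2 * w_in)
        axes = axes_per_level[lvl]
        w_out = p["W"].shape[1]
        pre = np.empty((B, n // 2, w_out))
        for d in range(3):
            mask = axes == d
            if mask.any():
                pre[mask] = cc[mask] @ p["W"][d].T + p["b"][d]
        out = relu(pre)
        cache.append({"cc": cc, "pre": pre, "axes": axes})
        reps = out
    root = reps[:, 0, :]
    scores = root @ model.fc["W"].T + model.fc["b"]
    cache.append({"root": root})
    return scores, cache


def _backward(model: KdNetModel, cache: list, dscores: np.ndarray,
              fc_only: bool = False) -> dict:
    """Gradients of the loss w.r.t. all parameters (summed over the batch)."""
    root = cache[-1]["root"]
    grads = {"fc_W": dscores.T @ root, "fc_b": dscores.sum(axis=0),
             "levels": [None] * len(model.level_params)}
    if fc_only:
        return grads
    droot = dscores @ model.fc["W"]          # (B, w_root)
    dout = droot[:, None, :]                 # (B, 1, w_root)
    for lvl in range(len(model.level_params) - 1, -1, -1):
        p = model.level_params[lvl]
        c = cache[lvl]
        dpre = dout * (c["pre"] > 0)
        dW = np.zeros_like(p["W"])
        db = np.zeros_like(p["b"])
        dcc = np.empty_like(c["cc"])
        for d in range(3):
            mask = c["axes"] == d
            if mask.any():
                dW[d] = np.einsum("no,ni->oi", dpre[mask], c["cc"][mask])
                db[d] = dpre[mask].sum(axis=0)
                dcc[mask] = dpre[mask] @ p["W"][d]
        grads["levels"][lvl] = {"W": dW, "b": db}
        B, n_par, two_w = dcc.shape
        dout = dcc.reshape(B, 2 * n_par, two_w // 2)
    return grads


def _prepare_batch(model: KdNetModel, clouds: list, tree_seeds) -> tuple:
    leaf_pts = []
    axes_per_level = [[] for _ in range(model.depth)]
    for cloud, s in zip(clouds, tree_seeds):
        canon = PointCloud(_canonicalize(cloud.points))
        tree = build_kdtree(canon, model.depth, seed=int(s))
        leaf_pts.append(tree.points[tree.leaf_order])
        for lvl in range(model.depth):
            axes_per_level[lvl].append(tree.level_axes(lvl))
    leaf = np.stack(leaf_pts)
    axes = [np.stack(a) for a in axes_per_level]
    return leaf, axes


def kdnet_forward(model: KdNetModel, tree: KdTreeIndex,
                  cloud: PointCloud | None = None) -> np.ndarray:
    """Class-score vector for one pre-built tree index.

    The leaf representations are the (already resampled) tree points in
    leaf order; *cloud* is accepted for interface symmetry but the tree
    already carries the resampled coordinates.
    """
    if tree.depth != model.depth:
        raise ParameterError(
            f"tree depth {tree.depth} != model depth {model.depth}")
    leaf = tree.points[tree.leaf_order][None, :, :]
    axes = [tree.level_axes(l)[None, :] for l in range(model.depth)]
    scores, _ = _forward_cached(model, leaf, axes)
    return scores[0]


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def root_features(model: KdNetModel, clouds: list, seed: int = 0,
                  n_trees: int = 5) -> np.ndarray:
    """Root representations averaged over several tree indexings per cloud.

    A single tree is a randomized view of the cloud (the resampling and the
    median splits depend on its seed); averaging the root representation
    over a few independently seeded trees removes most of that indexing
    noise and gives every cloud a stable embedding.
    """
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_trees):
        seeds = rng.integers(0, 2 ** 31, size=len(clouds))
        leaf, axes = _prepare_batch(model, clouds, seeds)
        _, cache = _forward_cached(model, leaf, axes)
        root = cache[-1]["root"]
        acc = root if acc is None else acc + root
    return acc / n_trees


def predict_proba(model: KdNetModel, clouds: list, seed: int = 0,
                  n_trees: int = 5) -> np.ndarray:
    """Class probabilities from the tree-averaged root representation."""
    root = root_features(model, clouds, seed=seed, n_trees=n_trees)
    scores = root @ model.fc["W"].T + model.fc["b"]
    return _softmax(scores)


def predict(model: KdNetModel, clouds: list, seed: int = 0,
            n_trees: int = 5) -> np.ndarray:
    """Predicted class indices (multi-tree vote)."""
    return np.argmax(predict_proba(model, clouds, seed, n_trees), axis=1)


def _sgd_step(model: KdNetModel, grads: dict, lr: float, batch: int) -> None:
    norm = batch
    model.fc["W"] -= lr * grads["fc_W"] / norm
    model.fc["b"] -= lr * grads["fc_b"] / norm
    if model.frozen:
        return
    for p, g in zip(model.level_params, grads["levels"]):
        if g is not None:
            p["W"] -= lr * g["W"] / norm
            p["b"] -= lr * g["b"] / norm


def weighted_cross_entropy(model: KdNetModel, clouds: list, labels: np.ndarray,
                           weights: np.ndarray, seed: int = 0) -> float:
    """Sum of per-example weight x cross-entropy (no renormalization):
    doubling an example's weight doubles its loss contribution exactly."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=len(clouds))
    leaf, axes = _prepare_batch(model, clouds, seeds)
    scores, _ = _forward_cached(model, leaf, axes)
    probs = _softmax(scores)
    nll = -np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-12, None))
    return float((weights * nll).sum())


def train_epoch(model: KdNetModel, clouds: list, labels: np.ndarray,
                cfg: TrainConfig, rng: np.random.Generator,
                weights: np.ndarray | None = None) -> float:
    """One SGD epoch with freshly seeded trees; returns the mean loss."""
    n = len(clouds)
    order = rng.permutation(n)
    tree_seeds = rng.integers(0, 2 ** 31, size=n)
    total = 0.0
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        leaf, axes = _prepare_batch(model, [clouds[i] for i in idx],
                                    tree_seeds[idx])
        scores, cache = _forward_cached(model, leaf, axes)
        probs = _softmax(scores)
        y = labels[idx]
        nll = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        w = np.ones(len(y)) if weights is None else weights[idx]
        total += float((w * nll).sum())
        dscores = probs.copy()
        dscores[np.arange(len(y)), y] -= 1.0
        dscores *= w[:, None]
        grads = _backward(model, cache, dscores, fc_only=model.frozen)
        # mean over the batch in both the weighted and unweighted case:
        # weights rescaled to mean ~1 then keep the step size comparable
        _sgd_step(model, grads, cfg.learning_rate, len(y))
    if not np.isfinite(total):
        raise TrainingError(f"loss diverged to {total}; lower the learning rate")
    return total / n


def evaluate(model: KdNetModel, clouds: list, labels: np.ndarray,
             seed: int = 0, n_trees: int = 5) -> float:
    """Classification accuracy over a list of clouds."""
    pred = predict(model, clouds, seed=seed, n_trees=n_trees)
    return float((pred == np.asarray(labels)).mean())


def train_kdnet(data: LabeledCloudSet, cfg: TrainConfig, depth: int = 7,
                model: KdNetModel | None = None,
                ) -> tuple[KdNetModel, list[float]]:
    """Train a classifier on a labeled cloud set.

    A stratified holdout split (``cfg.holdout_fraction``) is evaluated after
    every epoch; returns the trained model and the per-epoch holdout
    accuracy history. Fully reproducible under ``cfg.seed``.
    """
    labels = np.asarray(data.labels)
    n_classes = len(data.class_names)
    if n_classes < 2:
        raise ParameterError("need at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = KdNetModel.initialize(depth, n_classes,
                                      seed=int(rng.integers(2 ** 31)),
                                      class_names=list(data.class_names))

    # stratified holdout
    train_idx, hold_idx = [], []
    for c in range(n_classes):
        idx = np.nonzero(labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(len(idx) * cfg.holdout_fraction)))
        hold_idx.extend(idx[:k])
        train_idx.extend(idx[k:])
    train_idx, hold_idx = np.array(train_idx), np.array(hold_idx)
    tr_clouds = [data.clouds[i] for i in train_idx]
    ho_clouds = [data.clouds[i] for i in hold_idx]

    history = []
    eval_seed = int(rng.integers(2 ** 31))  # fixed: holdout trees identical
    for epoch in range(cfg.epochs):
        loss = train_epoch(model, tr_clouds, labels[train_idx], cfg, rng)
        acc = evaluate(model, ho_clouds, labels[hold_idx], seed=eval_seed)
        history.append(acc)
        if epoch % 10 == 0 or epoch == cfg.epochs - 1:
            logger.info("epoch %d: loss %.4f, holdout acc %.3f",
                        epoch, loss, acc)
    return model, history
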