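"""Instance-transfer of a pre-trained classifier to the cattle/other task.

The pre-trained tree levels are frozen (their gradients are never applied)
and the fully connected head is replaced by a freshly initialized two-class
map. The head is then retrained on a mix of source examples (the generic
shape corpus, all labeled "other") and the small labeled target set, with
boosting-style instance re-weighting: after each boosting round,
misclassified *source* examples are down-weighted by a fixed factor
beta_source = 1 / (1 + sqrt(2 ln n_source / N)) — unhelpful source
knowledge fades — while misclassified *target* examples are up-weighted by
(err / (1 - err))^-1 with err the weighted target error rate, focusing the
head on the hard target examples. The model with the best validation
accuracy over all rounds is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud
from .errors import BoostingStoppedError, ParameterError
from .kdnet import (KdNetModel, TrainConfig, _softmax, build_kdtree,
                    evaluate, kdnet_forward, predict, root_features,
                    train_epoch)
from .synth import LabeledCloudSet

logger = logging.getLogger(__name__)


@dataclass
class InstanceWeights:
    """Per-example boosting weights over source and target sets."""

    source_w: np.ndarray
    target_w: np.ndarray
    beta_source: float
    iteration: int = 0

    def __post_init__(self) -> None:
        self.source_w = np.asarray(self.source_w, dtype=np.float64)
        self.target_w = np.asarray(self.target_w, dtype=np.float64)
        if np.any(self.source_w <= 0) or np.any(self.target_w <= 0):
            raise ParameterError("all instance weights must be > 0")

    def normalized(self) -> "InstanceWeights":
        total = self.source_w.sum() + self.target_w.sum()
        return InstanceWeights(self.source_w / total, self.target_w / total,
                               self.beta_source, self.iteration)


def init_instance_weights(n_source: int, n_target: int, n_boost: int
                          ) -> InstanceWeights:
    """Uniform starting weights; beta_source fixed from (n_source, N)."""
    if n_source < 1 or n_target < 1 or n_boost < 1:
        raise ParameterError("n_source, n_target and n_boost must be >= 1")
    beta = 1.0 / (1.0 + np.sqrt(2.0 * np.log(n_source) / n_boost))
    w = np.full(n_source + n_target, 1.0 / (n_source + n_target))
    return InstanceWeights(w[:n_source], w[n_source:], beta_source=float(beta))


def tradaboost_update(weights: InstanceWeights, source_errors: np.ndarray,
                      target_errors: np.ndarray, target_error_rate: float
                      ) -> InstanceWeights:
    """One boosting re-weighting step.

    ``source_errors`` / ``target_errors`` are 0/1 misclassification flags.
    Raises :class:`~bovimetry.errors.BoostingStoppedError` when the weighted
    target error rate reaches 0.5 (the weak-learner condition fails).
    """
    if not 0.0 <= target_error_rate < 0.5:
        raise BoostingStoppedError(
            f"target error rate {target_error_rate:.3f} >= 0.5; boosting stops")
    src = weights.source_w * np.where(np.asarray(source_errors) > 0,
                                      weights.beta_source, 1.0)
    if target_error_rate == 0.0:
        tgt = weights.target_w.copy()
    else:
        beta_t = target_error_rate / (1.0 - target_error_rate)
        tgt = weights.target_w * np.where(np.asarray(target_errors) > 0,
                                          1.0 / beta_t, 1.0)
    return InstanceWeights(src, tgt, weights.beta_source,
                           weights.iteration + 1).normalized()


def _head_epoch(model: KdNetModel, feats: np.ndarray, labels: np.ndarray,
                weights: np.ndarray, cfg: TrainConfig,
                rng: np.random.Generator) -> None:
    """One weighted SGD epoch of the fully connected head on fixed features."""
    n = len(labels)
    order = rng.permutation(n)
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        x, y, w = feats[idx], labels[idx], weights[idx]
        scores = x @ model.fc["W"].T + model.fc["b"]
        probs = _softmax(scores)
        d = probs.copy()
        d[np.arange(len(y)), y] -= 1.0
        d *= w[:, None]
        model.fc["W"] -= cfg.learning_rate * (d.T @ x) / len(y)
        model.fc["b"] -= cfg.learning_rate * d.sum(axis=0) / len(y)


def freeze_and_rewire(model: KdNetModel, n_classes_new: int,
                      seed: int = 0, class_names: list | None = None
                      ) -> KdNetModel:
    """Freeze the tree levels, replace the head with a fresh n-class map."""
    if n_classes_new < 2:
        raise ParameterError("n_classes_new must be >= 2")
    rng = np.random.default_rng(seed)
    out = model.copy()
    out.frozen = True
    out.n_classes = n_classes_new
    w_root = model.fc["W"].shape[1]
    out.fc = {"W": rng.normal(scale=np.sqrt(1.0 / w_root),
                              size=(n_classes_new, w_root)),
              "b": np.zeros(n_classes_new)}
    out.class_names = class_names
    return out


def transfer_train(model: KdNetModel, source: LabeledCloudSet,
                   target: LabeledCloudSet, cfg: TrainConfig,
                   n_boost: int = 5, augment_target: bool = False
                   ) -> tuple[KdNetModel, list[float]]:
    """Freeze + head retraining with boosting-weighted source/target mix.

    *target* must carry binary labels (class 1 = the subject class). Source
    examples all act as class 0 ("other"). Per boosting round: the head is
    retrained for ``cfg.epochs`` epochs on the weighted combined set, the
    weights are updated from the round's misclassifications, and validation
    accuracy on a held-out target split is recorded; the best-validation
    model is returned. Deterministic under ``cfg.seed``.

    With ``augment_target`` the *training* portion of the target split is
    expanded ten-fold by the rotation/mirror augmentation — the standard
    recourse when the target set is small — while validation stays on
    unaugmented held-out originals.
    """
    if len(target) == 0:
        raise ParameterError("target set is empty")
    if len(target.class_names) != 2:
        raise ParameterError("target must be a 2-class set")
    rng = np.random.default_rng(cfg.seed)
    work = freeze_and_rewire(model, 2, seed=int(rng.integers(2 ** 31)),
                             class_names=list(target.class_names))

    tgt_labels = np.asarray(target.labels)
    # held-out target validation split (stratified)
    val_idx, fit_idx = [], []
    for c in (0, 1):
        idx = np.nonzero(tgt_labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(len(idx) * cfg.holdout_fraction)))
        val_idx.extend(idx[:k])
        fit_idx.extend(idx[k:])
    val_idx, fit_idx = np.array(val_idx), np.array(fit_idx)

    fit_clouds = [target.clouds[i] for i in fit_idx]
    fit_labels = list(tgt_labels[fit_idx])
    if augment_target:
        from .augment import augment_cloud
        aug_clouds, aug_labels = [], []
        for c, l in zip(fit_clouds, fit_labels):
            variants = augment_cloud(c)
            aug_clouds.extend(variants)
            aug_labels.extend([l] * len(variants))
        fit_clouds, fit_labels = aug_clouds, aug_labels
    clouds = list(source.clouds) + fit_clouds
    labels = np.concatenate([np.zeros(len(source.clouds), dtype=int),
                             np.asarray(fit_labels, dtype=int)])
    n_src, n_tgt = len(source.clouds), len(fit_clouds)
    weights = init_instance_weights(n_src, n_tgt, n_boost)

    val_clouds = [target.clouds[i] for i in val_idx]
    val_labels = tgt_labels[val_idx]
    eval_seed = int(rng.integers(2 ** 31))

    best_acc, best_model = -1.0, work.copy()
    history = []
    for it in range(n_boost):
        w_all = np.concatenate([weights.source_w, weights.target_w])
        # scale so the mean weight is 1: the SGD step size then matches the
        # unweighted case regardless of how many examples share the mass
        w_scaled = w_all * len(w_all)
        # the levels are frozen, so every example's tree-averaged root
        # representation is a fixed feature vector this round; the head is
        # fitted on exactly the representation used at prediction time
        feats = root_features(work, clouds, seed=int(rng.integers(2 ** 31)))
        for _ in range(cfg.epochs):
            _head_epoch(work, feats, labels, w_scaled, cfg, rng)
        scores = feats @ work.fc["W"].T + work.fc["b"]
        pred = np.argmax(scores, axis=1)
        errors = (pred != labels).astype(float)
        src_err, tgt_err = errors[:n_src], errors[n_src:]
        tw = weights.target_w
        rate = float((tw * tgt_err).sum() / tw.sum()) if tw.sum() > 0 else 0.0
        acc = evaluate(work, val_clouds, val_labels, seed=eval_seed)
        history.append(acc)
        logger.info("boost round %d: target err %.3f, val acc %.3f",
                    it, rate, acc)
        if acc > best_acc:
            best_acc, best_model = acc, work.copy()
        if it < n_boost - 1:
            try:
                weights = tradaboost_update(weights, src_err, tgt_err, rate)
            except BoostingStoppedError:
                logger.warning("boosting stopped early at round %d", it)
                break
    return best_model, history


def classify(model: KdNetModel, cloud: PointCloud, seed: int = 0,
             n_trees: int = 5) -> tuple[str | int, float]:
    """Classify one cloud; returns (label, mean softmax score of the label).

    Probabilities are averaged over ``n_trees`` seeded tree indexings. Ties
    break deterministically to the lower class index. The label is the
    class name when the model carries names.
    """
    from .kdnet import predict_proba
    probs = predict_proba(model, [cloud], seed=seed, n_trees=n_trees)[0]
    idx = int(np.argmax(probs))
    label = model.class_names[idx] if model.class_names else idx
    return label, float(probs[idx])
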