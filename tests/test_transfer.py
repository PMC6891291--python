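import numpy as np
import pytest

from bovimetry.errors import BoostingStoppedError, ParameterError
from bovimetry.kdnet import (KdNetModel, TrainConfig, train_kdnet,
                             weighted_cross_entropy)
from bovimetry.synth import generate_shape_dataset, make_transfer_dataset
from bovimetry.transfer import (InstanceWeights, classify, freeze_and_rewire,
                                init_instance_weights, tradaboost_update,
                                transfer_train)


class TestInstanceWeights:
    def test_beta_source_formula(self):
        w = init_instance_weights(100, 10, 10)
        assert w.beta_source == pytest.approx(
            1.0 / (1.0 + np.sqrt(2 * np.log(100) / 10)), abs=1e-9)
        assert w.beta_source == pytest.approx(0.5103, abs=2e-4)

    def test_no_errors_leaves_weights_unchanged(self):
        w = init_instance_weights(5, 5, 3)
        out = tradaboost_update(w, np.zeros(5), np.zeros(5), 0.0)
        np.testing.assert_allclose(out.source_w, w.source_w)
        np.testing.assert_allclose(out.target_w, w.target_w)

    def test_misclassified_source_down_weighted(self):
        w = init_instance_weights(4, 4, 3)
        errs = np.array([1.0, 0, 0, 0])
        out = tradaboost_update(w, errs, np.zeros(4), 0.25)
        assert out.source_w[0] < out.source_w[1]

    def test_misclassified_target_up_weighted(self):
        w = init_instance_weights(4, 4, 3)
        errs = np.array([1.0, 0, 0, 0])
        out = tradaboost_update(w, np.zeros(4), errs, 0.25)
        assert out.target_w[0] > out.target_w[1]

    def test_normalization_and_positivity(self):
        w = init_instance_weights(7, 3, 5)
        out = tradaboost_update(w, np.ones(7), np.array([1.0, 0, 1.0]), 0.3)
        total = out.source_w.sum() + out.target_w.sum()
        assert total == pytest.approx(1.0)
        assert np.all(out.source_w > 0) and np.all(out.target_w > 0)

    def test_boosting_stops_at_half_error(self):
        w = init_instance_weights(4, 4, 3)
        with pytest.raises(BoostingStoppedError):
            tradaboost_update(w, np.zeros(4), np.ones(4), 0.5)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ParameterError):
            InstanceWeights(np.array([0.0]), np.array([1.0]), 0.5)


class TestFreezeRewire:
    @pytest.fixture(scope="class")
    def pretrained(self):
        data = generate_shape_dataset(4, 8, 16, seed=3)
        cfg = TrainConfig(epochs=5, learning_rate=0.003, seed=1)
        model, _ = train_kdnet(data, cfg, depth=4)
        return model

    def test_levels_bit_identical_head_replaced(self, pretrained):
        out = freeze_and_rewire(pretrained, 2, seed=5)
        assert out.frozen and out.n_classes == 2
        for a, b in zip(pretrained.level_params, out.level_params):
            np.testing.assert_array_equal(a["W"], b["W"])
            np.testing.assert_array_equal(a["b"], b["b"])
        assert out.fc["W"].shape[0] == 2

    def test_gradient_step_leaves_levels_untouched(self, pretrained):
        data = generate_shape_dataset(2, 4, 16, seed=9)
        work = freeze_and_rewire(pretrained, 2, seed=5)
        before = [p["W"].copy() for p in work.level_params]
        fc_before = work.fc["W"].copy()
        from bovimetry.kdnet import train_epoch
        rng = np.random.default_rng(0)
        train_epoch(work, data.clouds, np.asarray(data.labels),
                    TrainConfig(epochs=1, learning_rate=0.01, seed=0), rng)
        for a, b in zip(before, work.level_params):
            np.testing.assert_array_equal(a, b["W"])
        assert not np.array_equal(fc_before, work.fc["W"])

    def test_root_representation_unchanged_by_rewire(self, pretrained, rng):
        from bovimetry.cloud import PointCloud
        from bovimetry.kdnet import (_canonicalize, _forward_cached,
                                     build_kdtree)
        cloud = PointCloud(rng.normal(size=(16, 3)))
        canon = PointCloud(_canonicalize(cloud.points))
        tree = build_kdtree(canon, 4, seed=3)
        leaf = tree.points[tree.leaf_order][None]
        axes = [tree.level_axes(l)[None] for l in range(4)]
        _, c1 = _forward_cached(pretrained, leaf, axes)
        rewired = freeze_and_rewire(pretrained, 2, seed=5)
        _, c2 = _forward_cached(rewired, leaf, axes)
        np.testing.assert_array_equal(c1[-1]["root"], c2[-1]["root"])

    def test_too_few_classes_rejected(self, pretrained):
        with pytest.raises(ParameterError):
            freeze_and_rewire(pretrained, 1)


class TestTransferTrain:
    @pytest.fixture(scope="class")
    def pretrained(self):
        data = generate_shape_dataset(4, 8, 16, seed=3)
        model, _ = train_kdnet(data, TrainConfig(epochs=5, learning_rate=0.003,
                                                 seed=1), depth=4)
        return model

    def test_zero_lr_single_round_returns_rewired_init(self, pretrained):
        source = generate_shape_dataset(4, 4, 16, seed=5)
        target = make_transfer_dataset(8, 8, 16, seed=6)
        cfg = TrainConfig(epochs=1, learning_rate=0.0, seed=4)
        model, hist = transfer_train(pretrained, source, target, cfg,
                                     n_boost=1)
        assert len(hist) == 1
        # frozen levels identical; head untouched by the zero-lr epochs
        for a, b in zip(pretrained.level_params, model.level_params):
            np.testing.assert_array_equal(a["W"], b["W"])

    def test_doubling_weight_doubles_loss_contribution(self, pretrained):
        target = make_transfer_dataset(4, 4, 16, seed=8)
        labels = np.asarray(target.labels)
        w = np.ones(len(labels))
        base = weighted_cross_entropy(pretrained_head(pretrained),
                                      target.clouds, labels, w, seed=3)
        w2 = w.copy()
        w2[0] = 2.0
        doubled = weighted_cross_entropy(pretrained_head(pretrained),
                                         target.clouds, labels, w2, seed=3)
        only0 = weighted_cross_entropy(
            pretrained_head(pretrained), target.clouds, labels,
            np.eye(len(labels))[0], seed=3)
        assert doubled == pytest.approx(base + only0, rel=1e-12)

    def test_empty_target_rejected(self, pretrained):
        source = generate_shape_dataset(4, 4, 16, seed=5)
        with pytest.raises((ParameterError, Exception)):
            transfer_train(pretrained, source,
                           make_transfer_dataset(0, 0, 16, seed=1),
                           TrainConfig(epochs=1, learning_rate=0.1, seed=0))

    def test_classify_deterministic_and_tied(self, pretrained):
        target = make_transfer_dataset(4, 4, 16, seed=8)
        model = freeze_and_rewire(pretrained, 2, seed=5,
                                  class_names=["other", "cattle"])
        l1, s1 = classify(model, target.clouds[0], seed=3)
        l2, s2 = classify(model, target.clouds[0], seed=3)
        assert (l1, s1) == (l2, s2)
        # exact ties break to the lower class index
        model.fc["W"][:] = 0.0
        model.fc["b"][:] = 0.0
        label, score = classify(model, target.clouds[0], seed=3)
        assert label == "other" and score == pytest.approx(0.5)


def pretrained_head(model):
    out = freeze_and_rewire(model, 2, seed=7)
    return out
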