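import numpy as np
import pytest

from bovimetry.cloud import PointCloud
from bovimetry.errors import AuxiliaryPointError, ParameterError
from bovimetry.measure import (REFERENCE_MEASUREMENTS, BodyDimensions,
                               MeasureConfig, compute_dimensions,
                               derive_auxiliary_points, error_percent,
                               error_report, measure_pipeline)
from bovimetry.segment import PlaneModel
from bovimetry.synth import generate_scene


def flat_ground():
    return PlaneModel(np.array([0.0, 1.0, 0.0]), 0.0, np.array([], dtype=int))


class TestErrorReport:
    @pytest.mark.parametrize("auto,manual,expected", [
        (1.387, 1.355, 2.36),   # largest body-length deviation on record
        (0.610, 0.619, 1.45),   # chest depth
        (1.256, 1.255, 0.08),   # withers height
        (1.133, 1.134, 0.09),   # back height
        (1.213, 1.211, 0.17),   # withers height
    ])
    def test_reference_cells(self, auto, manual, expected):
        assert error_percent(auto, manual) == expected

    def test_equal_measurements_zero(self):
        assert error_percent(0.5, 0.5) == 0.0

    def test_rounding_half_up(self):
        # 0.125% must round to 0.13, not 0.12
        assert error_percent(1.00125, 1.0) == 0.13

    def test_nonpositive_manual_rejected(self):
        with pytest.raises(ParameterError):
            error_percent(1.0, 0.0)

    def test_full_reference_table_reproduced(self):
        """Every recorded error cell of the three reference animals is
        reproduced exactly from its automatic/manual pair."""
        expected = {
            "Q0392": {"withers_height": 0.17, "chest_depth": 0.16,
                      "back_height": 1.26, "waist_height": 0.94,
                      "body_length": 2.36},
            "Q0526": {"withers_height": 0.08, "chest_depth": 1.45,
                      "back_height": 1.19, "waist_height": 0.16,
                      "body_length": 0.28},
            "Q0456": {"withers_height": 0.32, "chest_depth": 0.31,
                      "back_height": 0.09, "waist_height": 0.26,
                      "body_length": 0.19},
        }
        for tag, ref in REFERENCE_MEASUREMENTS.items():
            rep = error_report(ref["automatic"], ref["manual"])
            got = {k: r["error_percent"] for k, r in rep.rows.items()}
            assert got == expected[tag], tag

    def test_missing_dimension_rejected(self):
        with pytest.raises(ParameterError):
            error_report({"withers_height": 1.0}, {"withers_height": 1.0})


class TestAuxiliaryPoints:
    def _landmarks(self):
        return {
            "withers_upper": np.array([-0.5, 1.21, 0.0]),
            "back_upper": np.array([0.0, 1.15, 0.0]),
            "waist_upper": np.array([0.4, 1.18, 0.0]),
            "chest_lower": np.array([-0.2, 0.47, 0.0]),
            "bodylen_upper": np.array([-0.8, 0.9, 0.0]),
            "bodylen_lower": np.array([0.7, 0.9, 0.0]),
        }

    def test_flat_ground_lower_points(self):
        cloud = PointCloud([[-0.2, 1.10, 0.0], [-0.2, 0.8, 0.0]])
        aux = derive_auxiliary_points(self._landmarks(), flat_ground(), cloud,
                                      chest_cylinder_radius=0.05)
        np.testing.assert_allclose(aux["withers_lower"], [-0.5, 0, 0],
                                   atol=1e-12)
        np.testing.assert_allclose(aux["chest_upper"], [-0.2, 1.10, 0],
                                   atol=1e-12)

    def test_tilted_ground_lower_point_on_plane(self):
        n = np.array([0.1, 1.0, -0.05])
        ground = PlaneModel(n, -0.3, np.array([], dtype=int))
        # one cloud point exactly on the chest axis (along the plane normal)
        chest = self._landmarks()["chest_lower"]
        cloud = PointCloud([chest + 0.6 * ground.normal])
        aux = derive_auxiliary_points(self._landmarks(), ground, cloud,
                                      chest_cylinder_radius=0.05)
        for name in ("withers_lower", "back_lower", "waist_lower"):
            assert abs(ground.distance(aux[name][None])[0]) < 1e-9

    def test_empty_cylinder_rejected(self):
        cloud = PointCloud([[5.0, 1.0, 5.0]])
        with pytest.raises(AuxiliaryPointError):
            derive_auxiliary_points(self._landmarks(), flat_ground(), cloud,
                                    chest_cylinder_radius=0.01)


class TestComputeDimensions:
    def test_textbook_values(self):
        lm = {
            "withers_upper": [-0.5, 1.21, 0.0],
            "back_upper": [0.0, 1.15, 0.0],
            "waist_upper": [0.4, 1.18, 0.0],
            "chest_lower": [-0.2, 0.47, 0.0],
            "bodylen_upper": [-0.8, 0.9, 0.0],
            "bodylen_lower": [0.7, 0.9, 0.0],
        }
        aux = {"chest_upper": np.array([-0.2, 1.10, 0.0])}
        dims = compute_dimensions(lm, aux, flat_ground())
        assert dims.withers_height == pytest.approx(1.21)
        assert dims.back_height == pytest.approx(1.15)
        assert dims.waist_height == pytest.approx(1.18)
        assert dims.chest_depth == pytest.approx(0.63)
        assert dims.body_length == pytest.approx(1.5)

    def test_as_dict_round_trip_through_report(self):
        d = BodyDimensions(1.2, 0.6, 1.1, 1.15, 1.5)
        rep = error_report(d, d.as_dict())
        assert rep.mean_error_percent == 0.0


class TestPipeline:
    def test_landmarks_recovered_near_truth(self, feature_db):
        cloud, truth = generate_scene(seed=2)
        res = measure_pipeline(cloud, feature_db, MeasureConfig(seed=2))
        for name, p in res.dimensions.landmarks.items():
            d = np.linalg.norm(p - truth.landmarks_true[name])
            assert d <= 3 * truth.sampling_step + 0.05, (name, d)

    def test_dimensions_close_to_truth(self, feature_db):
        cloud, truth = generate_scene(seed=3)
        res = measure_pipeline(cloud, feature_db, MeasureConfig(seed=3))
        meas = res.dimensions.as_dict()
        for k, v in meas.items():
            rel = abs(v - truth.dimensions_true[k]) / truth.dimensions_true[k]
            assert rel < 0.05, (k, rel)

    def test_report_attached_when_manual_given(self, feature_db):
        cloud, truth = generate_scene(seed=4)
        res = measure_pipeline(cloud, feature_db, MeasureConfig(seed=4),
                               manual=truth.dimensions_true)
        assert res.report is not None
        assert res.report.mean_error_percent < 5.0

    def test_rigid_invariance_of_dimensions(self, feature_db):
        from bovimetry.synth import _rot_y
        cloud, truth = generate_scene(seed=5)
        res0 = measure_pipeline(cloud, feature_db, MeasureConfig(seed=5))
        R = _rot_y(0.7)
        moved = PointCloud(cloud.points @ R.T + np.array([0.3, 0.0, -0.2]))
        res1 = measure_pipeline(moved, feature_db, MeasureConfig(seed=5))
        a, b = res0.dimensions.as_dict(), res1.dimensions.as_dict()
        for k in a:
            # body length rests on two small recognized bumps and is the
            # least stable dimension (it also shows the largest errors in
            # the reference measurements); heights are plane distances and
            # reproduce tightly
            tol = 0.04 if k == "body_length" else 0.02
            assert abs(a[k] - b[k]) / a[k] < tol, (k, a[k], b[k])

    def test_scale_equivariance(self, feature_db):
        s = 1.1
        cloud, truth = generate_scene(seed=6)
        res0 = measure_pipeline(cloud, feature_db, MeasureConfig(seed=6))
        scaled = PointCloud(cloud.points * s)
        res1 = measure_pipeline(scaled, feature_db, MeasureConfig(seed=6))
        a, b = res0.dimensions.as_dict(), res1.dimensions.as_dict()
        for k in a:
            tol = 0.04 if k == "body_length" else 0.02
            assert abs(b[k] - s * a[k]) / (s * a[k]) < tol, (k, a[k], b[k])

    def test_classifier_gate_rejects_non_cattle(self, feature_db):
        from bovimetry.errors import NotCattleError
        from bovimetry.kdnet import KdNetModel
        cloud, _ = generate_scene(seed=8)
        gate = KdNetModel.initialize(4, 2, seed=0,
                                     class_names=["other", "cattle"])
        # a head that always answers "other": the pipeline must refuse
        gate.fc["W"][:] = 0.0
        gate.fc["b"][:] = [5.0, -5.0]
        cfg = MeasureConfig(seed=8, use_classifier_gate=True)
        with pytest.raises(NotCattleError):
            measure_pipeline(cloud, feature_db, cfg, classifier=gate)

    def test_first_match_determinism(self, feature_db):
        cloud, _ = generate_scene(seed=7)
        r1 = measure_pipeline(cloud, feature_db, MeasureConfig(seed=7))
        r2 = measure_pipeline(cloud, feature_db, MeasureConfig(seed=7))
        assert r1.dimensions.as_dict() == r2.dimensions.as_dict()
        for k in r1.dimensions.landmarks:
            np.testing.assert_array_equal(r1.dimensions.landmarks[k],
                                          r2.dimensions.landmarks[k])
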