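"""Angle-feature generation: combinatorics, geometry, invariances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmspose.landmarks import LANDMARK_NAMES, Landmark, LandmarkSet, ModeError, MovementTask
from cmspose.rom import (
    N_FEATURES_BOTH,
    N_FEATURES_PER_MODE,
    DegenerateVectorError,
    FeatureQualityError,
    angle_between,
    elevation_angle,
    feature_index,
    feature_names,
    generate_angle_features,
    vector_between,
)
from cmspose.synthetic import generate_posture

from conftest import make_set


class TestAngleBetween:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0), (0, 1), 90.0),
            ((1, 0), (2, 0), 0.0),
            ((1, 0), (-3, 0), 180.0),
            ((1, 0), (-1, 1), 135.0),
            ((1, 1, 0), (1, 1, 0), 0.0),
        ],
    )
    def test_analytic_angles(self, a, b, expected):
        # abs tolerance: arccos near cos=1 amplifies the last-ulp rounding
        # of the normalized dot product to ~1e-6 degrees
        assert angle_between(np.array(a), np.array(b)) == pytest.approx(expected, abs=1e-5)

    def test_zero_vector_is_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            angle_between(np.zeros(2), np.array([1.0, 0.0]))

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    def test_symmetric_and_bounded(self, ax, ay, bx, by):
        a, b = np.array([ax, ay]), np.array([bx, by])
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            return
        t1 = angle_between(a, b)
        assert 0.0 <= t1 <= 180.0
        assert t1 == pytest.approx(angle_between(b, a))


class TestVectorBetween:
    def test_componentwise_difference(self, ir_set):
        v = vector_between(ir_set, "shoulder_R", "elbow_R", "3D")
        e = np.array(ir_set.coords("elbow_R", "3D")) - np.array(ir_set.coords("shoulder_R", "3D"))
        assert np.allclose(v, e)

    def test_same_landmark_degenerate(self, ir_set):
        with pytest.raises(DegenerateVectorError):
            vector_between(ir_set, "nose", "nose", "2D")

    def test_3d_on_2d_set_is_mode_error(self):
        s = make_set({n: (0.1 * i, 0.2) for i, n in enumerate(LANDMARK_NAMES)})
        with pytest.raises(ModeError):
            vector_between(s, "nose", "hip_L", "3D")


class TestFeatureEnumeration:
    def test_counts_match_brute_force_combinatorics(self):
        # independent oracle: enumerate ordered landmark pairs then vector pairs
        pairs = [(i, j) for i in range(9) for j in range(9) if i != j]
        n_vec_pairs = len(list(itertools.combinations(range(len(pairs)), 2)))
        assert len(pairs) == 72
        assert n_vec_pairs == N_FEATURES_PER_MODE == 2556
        assert len(feature_index("2D")) == n_vec_pairs
        assert len(feature_index("both")) == 2 * n_vec_pairs == N_FEATURES_BOTH

    def test_feature_vector_lengths(self, ir_set):
        assert generate_angle_features(ir_set, "2D").values.shape == (2556,)
        assert generate_angle_features(ir_set, "3D").values.shape == (2556,)
        assert generate_angle_features(ir_set, "both").values.shape == (5112,)

    def test_index_mapping_total_and_injective(self):
        idx = feature_index("both")
        assert len(set(idx)) == len(idx)
        names = feature_names("both")
        assert len(set(names)) == len(names) == N_FEATURES_BOTH

    def test_both_concatenates_2d_then_3d(self, ir_set):
        both = generate_angle_features(ir_set, "both").values
        assert np.array_equal(both[:2556], generate_angle_features(ir_set, "2D").values)
        assert np.array_equal(both[2556:], generate_angle_features(ir_set, "3D").values)

    def test_values_match_scalar_path(self, noisy_ir_set):
        # vectorized block agrees with per-pair angle_between on a sample
        vals = generate_angle_features(noisy_ir_set, "2D").values
        idx = feature_index("2D")
        for k in (0, 17, 500, 2555):
            (f1, t1), (f2, t2), _ = idx[k]
            a = vector_between(noisy_ir_set, LANDMARK_NAMES[f1], LANDMARK_NAMES[t1], "2D")
            b = vector_between(noisy_ir_set, LANDMARK_NAMES[f2], LANDMARK_NAMES[t2], "2D")
            assert vals[k] == pytest.approx(angle_between(a, b), abs=1e-9)

    def test_angles_bounded_no_spurious_nan(self, noisy_ir_set):
        vals = generate_angle_features(noisy_ir_set, "both").values
        assert not np.isnan(vals).any()
        assert vals.min() >= 0.0 and vals.max() <= 180.0

    def test_mode_3d_on_2d_set_rejected(self):
        s = make_set({n: (0.1 * i, 0.2) for i, n in enumerate(LANDMARK_NAMES)})
        with pytest.raises(ModeError):
            generate_angle_features(s, "3D")

    def test_coincident_landmarks_yield_nan_sentinels(self, ir_set):
        lms = dict(ir_set.landmarks)
        lms["wrist_R"] = lms["elbow_R"]  # one collision
        s = LandmarkSet(lms, ir_set.task, ir_set.side)
        vals = generate_angle_features(s, "2D").values
        n_nan = int(np.isnan(vals).sum())
        # vectors touching the collided pair are undefined: the wrist_R<->elbow_R
        # directed vectors (2 of 72) appear in 2*71 - 1 pairs
        assert n_nan == 2 * 71 - 1
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 180.0

    def test_majority_missing_raises_quality_error(self):
        coords = {n: (0.5, 0.5) for n in LANDMARK_NAMES}
        coords["nose"] = (0.5, 0.1)
        s = make_set(coords)
        with pytest.raises(FeatureQualityError):
            generate_angle_features(s, "2D")


class TestGeometricInvariance:
    def _transformed(self, s, fn):
        lms = {
            n: Landmark(*fn(lm.x, lm.y), lm.z, lm.visibility) for n, lm in s.landmarks.items()
        }
        return LandmarkSet(lms, s.task, s.side)

    def test_translation_and_scale_invariance(self, noisy_ir_set):
        base = generate_angle_features(noisy_ir_set, "2D").values
        shifted = self._transformed(noisy_ir_set, lambda x, y: (x + 3.7, y - 1.2))
        scaled = self._transformed(noisy_ir_set, lambda x, y: (2.5 * x, 2.5 * y))
        assert np.allclose(base, generate_angle_features(shifted, "2D").values, atol=1e-8)
        assert np.allclose(base, generate_angle_features(scaled, "2D").values, atol=1e-8)

    def test_rotation_invariance_2d(self, noisy_ir_set):
        base = generate_angle_features(noisy_ir_set, "2D").values
        th = 0.83
        c, s_ = math.cos(th), math.sin(th)
        rotated = self._transformed(noisy_ir_set, lambda x, y: (c * x - s_ * y, s_ * x + c * y))
        assert np.allclose(base, generate_angle_features(rotated, "2D").values, atol=1e-7)

    def test_deterministic(self, noisy_ir_set):
        a = generate_angle_features(noisy_ir_set, "both").values
        b = generate_angle_features(noisy_ir_set, "both").values
        assert np.array_equal(a, b)


class TestElevationAngle:
    def _elev_set(self, shoulder, elbow, hip, task=MovementTask.lateral_elevation):
        coords = {
            "nose": (0.5, -0.5),
            "shoulder_L": (-1.0, 0.0),
            "elbow_L": (-1.0, 0.4),
            "wrist_L": (-1.0, 0.8),
            "hip_L": (-1.0, 1.0),
            "shoulder_R": shoulder,
            "elbow_R": elbow,
            "wrist_R": (elbow[0] * 1.5, elbow[1] * 1.5),
            "hip_R": hip,
        }
        return make_set(coords, task=task, side="right")

    def test_arm_along_trunk_is_zero(self):
        s = self._elev_set((0, 0), (0, 0.5), (0, 1))
        assert elevation_angle(s) == pytest.approx(0.0, abs=1e-9)

    def test_arm_perpendicular_is_ninety(self):
        s = self._elev_set((0, 0), (0.5, 0.0), (0, 1))
        assert elevation_angle(s) == pytest.approx(90.0)

    def test_hand_computed_oblique_angle(self):
        # arm (0.6, -0.8), trunk (0, 1): cos = -0.8 -> 143.130 degrees
        s = self._elev_set((0, 0), (0.6, -0.8), (0, 1))
        assert elevation_angle(s) == pytest.approx(math.degrees(math.acos(-0.8)), abs=1e-6)
        assert elevation_angle(s) == pytest.approx(143.13, abs=0.01)

    def test_wrong_task_rejected(self, ir_set):
        with pytest.raises(ValueError, match="elevation"):
            elevation_angle(ir_set)

    def test_uses_declared_affected_side(self):
        s = self._elev_set((0, 0), (0.5, 0.0), (0, 1))
        left = LandmarkSet(dict(s.landmarks), s.task, "left")
        assert elevation_angle(s) == pytest.approx(90.0)
        assert elevation_angle(left) == pytest.approx(0.0, abs=1e-6)  # left arm hangs down
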