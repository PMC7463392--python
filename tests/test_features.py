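import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exerscore import (
    all_builtin_specs,
    builtin_spec,
    default_params,
    drop_feature,
    extract_features,
    segment_vs_vertical_angle,
    simulate_feature_trajectory,
    simulate_skeleton_session,
    three_joint_angle,
)
from exerscore.features import FeatureTrajectory, load_features, load_spec, save_features, save_spec


class TestThreeJointAngle:
    @pytest.mark.parametrize(
        "a, c, expected",
        [
            ((0, 1, 0), (0, -1, 0), 180.0),  # collinear, opposite sides
            ((0, 1, 0), (1, 0, 0), 90.0),
            ((0, 1, 0), (1, 1, 0), 45.0),
            ((0, 1, 0), (0, 2, 0), 0.0),  # same direction
        ],
    )
    def test_closed_forms(self, a, c, expected):
        assert three_joint_angle(a, (0, 0, 0), c) == pytest.approx(expected, abs=1e-9)

    def test_coincident_joints_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            three_joint_angle((1, 1, 1), (1, 1, 1), (0, 0, 0))


class TestSegmentVsVertical:
    @pytest.mark.parametrize(
        "proximal, distal, expected",
        [
            ((0, 1, 0), (0, 0, 0), 0.0),  # hanging straight down
            ((0, 0, 0), (1, 0, 0), 90.0),  # horizontal
            ((0, 0, 0), (0, 1, 0), 180.0),  # straight up
        ],
    )
    def test_closed_forms(self, proximal, distal, expected):
        assert segment_vs_vertical_angle(proximal, distal) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            segment_vs_vertical_angle((1, 2, 3), (1, 2, 3))


@settings(deadline=None, max_examples=50)
@given(
    pts=st.lists(
        st.tuples(*[st.floats(-2, 2) for _ in range(3)]), min_size=3, max_size=3
    ),
    angle=st.floats(0, 2 * np.pi),
    scale=st.floats(0.1, 5.0),
    shift=st.tuples(*[st.floats(-10, 10) for _ in range(3)]),
)
def test_angle_invariance_under_rigid_transforms(pts, angle, scale, shift):
    """Angles are invariant to translation, uniform scaling, and rotation
    about the vertical axis applied to all joints."""
    a, b, c = (np.array(p, dtype=float) for p in pts)
    if (
        np.linalg.norm(a - b) < 1e-3
        or np.linalg.norm(c - b) < 1e-3
        or np.linalg.norm(c - a) < 1e-6
    ):
        return
    rot = np.array(
        [
            [np.cos(angle), 0.0, np.sin(angle)],
            [0.0, 1.0, 0.0],
            [-np.sin(angle), 0.0, np.cos(angle)],
        ]
    )
    shift = np.array(shift)

    def transform(p):
        return scale * (rot @ p) + shift

    original = three_joint_angle(a, b, c)
    moved = three_joint_angle(transform(a), transform(b), transform(c))
    assert moved == pytest.approx(original, abs=1e-6)

    original_sv = segment_vs_vertical_angle(a, b)
    moved_sv = segment_vs_vertical_angle(transform(a), transform(b))
    assert moved_sv == pytest.approx(original_sv, abs=1e-6)


class TestBuiltinSpecs:
    def test_seven_variants_with_expected_widths(self):
        specs = all_builtin_specs()
        assert len(specs) == 7
        for spec in specs:
            expected = 3 if spec.exercise == "lunge" else 2
            assert spec.n_features == expected

    def test_lunge_requires_side(self):
        with pytest.raises(ValueError):
            builtin_spec("lunge", "none")

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = builtin_spec("lunge", "right")
        save_spec(spec, tmp_path / "spec.yml")
        assert load_spec(tmp_path / "spec.yml") == spec


class TestExtractFeatures:
    def test_output_shape_matches_session_and_spec(self, small_session, shoulder_spec):
        traj = extract_features(small_session, shoulder_spec)
        assert traj.values.shape == (len(small_session), 2)

    def test_lunge_gives_three_columns(self):
        spec = builtin_spec("lunge", "left")
        session = simulate_skeleton_session(
            default_params(spec, seed=0, noise_sd=0.0, n_reps=1, pause_duration=0.3),
            spec,
        )
        traj = extract_features(session, spec)
        assert traj.values.shape[1] == 3

    def test_static_pose_gives_constant_rest_angles(self, shoulder_spec):
        params = default_params(
            shoulder_spec, seed=0, noise_sd=0.0, n_reps=1,
            peak_amplitudes=(0.0, 0.0), pause_duration=0.3, rep_duration=0.5,
        )
        traj = extract_features(simulate_skeleton_session(params, shoulder_spec), shoulder_spec)
        np.testing.assert_allclose(
            traj.values, np.tile(shoulder_spec.rest_pose_angles, (len(traj), 1)), atol=1e-9
        )

    def test_missing_joint_raises(self, small_session, shoulder_spec):
        broken = dataclasses.replace(small_session)
        for f in broken.frames:
            f.positions.pop("WristLeft", None)
        with pytest.raises(ValueError, match="required joint missing"):
            extract_features(broken, shoulder_spec)

    @pytest.mark.parametrize("spec", all_builtin_specs(), ids=lambda s: s.name)
    def test_simulator_round_trip_within_half_degree(self, spec):
        """Skeleton placement reproduces the prescribed angle curves."""
        params = default_params(spec, seed=0, noise_sd=0.0, n_reps=2,
                                rep_duration=1.0, pause_duration=0.5)
        session = simulate_skeleton_session(params, spec)
        extracted = extract_features(session, spec)
        prescribed = simulate_feature_trajectory(params, spec)
        assert np.max(np.abs(extracted.values - prescribed.values)) < 0.5


class TestDropFeature:
    def test_projection(self, shoulder_trajectory):
        reduced = drop_feature(shoulder_trajectory, 0)
        assert reduced.n_features == 1
        np.testing.assert_array_equal(reduced.values[:, 0], shoulder_trajectory.values[:, 1])

    def test_out_of_range_index(self, shoulder_trajectory):
        with pytest.raises(ValueError, match="out of range"):
            drop_feature(shoulder_trajectory, 5)

    def test_cannot_drop_last_column(self, shoulder_trajectory):
        single = drop_feature(shoulder_trajectory, 1)
        with pytest.raises(ValueError, match="last remaining"):
            drop_feature(single, 0)

    def test_main_feature_index_remapped(self):
        spec = builtin_spec("hip_abduction", "left")  # main feature is column 1
        traj = simulate_feature_trajectory(default_params(spec, seed=0), spec)
        reduced = drop_feature(traj, 0)
        assert reduced.spec.main_feature_index == 0
        np.testing.assert_array_equal(reduced.main, traj.main)


def test_feature_csv_round_trip(tmp_path, shoulder_trajectory):
    path = tmp_path / "f.csv"
    save_features(shoulder_trajectory, path)
    back = load_features(path, shoulder_trajectory.spec)
    np.testing.assert_allclose(back.values, shoulder_trajectory.values, atol=1e-5)
    np.testing.assert_allclose(back.timestamps, shoulder_trajectory.timestamps, atol=1e-5)


def test_trajectory_invariants_enforced(shoulder_spec):
    with pytest.raises(ValueError, match="\\[0, 360\\)"):
        FeatureTrajectory(np.array([[400.0, 10.0]]), np.array([0.0]), shoulder_spec)
    with pytest.raises(ValueError, match="feature count"):
        FeatureTrajectory(np.zeros((2, 3)), np.array([0.0, 0.1]), shoulder_spec)
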