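"""Joint-angle feature extraction.

Raw 3D joint positions depend on subject size and placement in front of the
camera, so exercises are described by invariant scalar features: interior
angles at a joint (three-joint angles) and limb-segment inclinations against
the body vertical.  A feature trajectory T is the l x d matrix of those
angles over l frames — d = 3 for the lunge, d = 2 for the other exercises.

The concrete joint triplets per exercise are a documented package choice
(the physical semantics — e.g. shoulder elevation as the main shoulder
abduction feature, elbow angle as arm straightness — follow the clinical
descriptions); every definition can be overridden through
:class:`ExerciseSpec` without code changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .skeleton import SkeletonSession, validate_joint

#: Downward body vertical used for segment inclination features.
DOWN = np.array([0.0, -1.0, 0.0])

EXERCISES = ("shoulder_abduction", "hip_abduction", "lunge", "sit_to_stand")
SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class AngleDefinition:
    """One scalar angle feature.

    kind ``three-joint``: interior angle at the vertex (second joint) between
    vectors to the first and third joints.  kind ``segment-vs-vertical``:
    angle of the proximal->distal segment against the downward vertical
    (0 deg = hanging straight down, 180 deg = straight up).
    """

    kind: str
    joints: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        expected = {"three-joint": 3, "segment-vs-vertical": 2}
        if self.kind not in expected:
            raise ValueError(f"unknown angle kind: {self.kind!r}")
        if len(self.joints) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} angle needs {expected[self.kind]} joints, "
                f"got {len(self.joints)}"
            )
        if len(set(self.joints)) != len(self.joints):
            raise ValueError("angle joints must be distinct")
        for j in self.joints:
            validate_joint(j)


@dataclass(frozen=True)
class ExerciseSpec:
    """Which angles describe an exercise, which one dominates, and the rest pose."""

    exercise: str
    side: str
    angles: tuple[AngleDefinition, ...]
    main_feature_index: int
    rest_pose_angles: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if not self.angles:
            raise ValueError("spec needs at least one angle")
        if not 0 <= self.main_feature_index < len(self.angles):
            raise ValueError("main_feature_index out of range")
        if len(self.rest_pose_angles) != len(self.angles):
            raise ValueError("rest_pose_angles length must match angle count")

    @property
    def n_features(self) -> int:
        return len(self.angles)

    @property
    def name(self) -> str:
        return self.exercise if self.side == "none" else f"{self.exercise}_{self.side}"

    def required_joints(self) -> set[str]:
        return {j for a in self.angles for j in a.joints}


@dataclass
class FeatureTrajectory:
    """The l x d matrix of joint-angle features (degrees) with timestamps."""

    values: np.ndarray
    timestamps: np.ndarray
    spec: ExerciseSpec

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values and timestamps length mismatch")
        if self.values.shape[1] != self.spec.n_features:
            raise ValueError("feature count does not match spec")
        if self.values.size and (self.values.min() < 0 or self.values.max() >= 360):
            raise ValueError("feature values must lie in [0, 360) degrees")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("non-monotonic timestamps")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def main(self) -> np.ndarray:
        """The dominant feature column."""
        return self.values[:, self.spec.main_feature_index]


def three_joint_angle(a, b, c) -> float:
    """Interior angle (degrees, in [0, 180]) at vertex ``b`` between b->a and b->c."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length limb vector (coincident joints)")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def segment_vs_vertical_angle(proximal, distal) -> float:
    """Angle (degrees, in [0, 180]) of proximal->distal against the downward vertical."""
    p = np.asarray(proximal, dtype=float)
    d = np.asarray(distal, dtype=float)
    v = d - p
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("coincident points")
    cosang = np.clip(np.dot(v, DOWN) / nv, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _evaluate_angle(angle: AngleDefinition, positions: dict[str, np.ndarray]) -> float:
    try:
        pts = [positions[j] for j in angle.joints]
    except KeyError as exc:
        raise ValueError(f"required joint missing from frame: {exc.args[0]}") from exc
    if angle.kind == "three-joint":
        return three_joint_angle(*pts)
    return segment_vs_vertical_angle(*pts)


def extract_features(session: SkeletonSession, spec: ExerciseSpec) -> FeatureTrajectory:
    """Evaluate the spec's angles on every frame of a session."""
    values = np.empty((len(session.frames), spec.n_features))
    for i, frame in enumerate(session.frames):
        for k, angle in enumerate(spec.angles):
            values[i, k] = _evaluate_angle(angle, frame.positions)
    return FeatureTrajectory(values, session.timestamps, spec)


def drop_feature(traj: FeatureTrajectory, index: int) -> FeatureTrajectory:
    """Remove one feature column, e.g. to measure the influence of a minor feature.

    The returned trajectory carries a reduced spec; if the dropped column was
    the main feature the first remaining column becomes main.
    """
    d = traj.n_features
    if d < 2:
        raise ValueError("cannot drop the last remaining feature")
    if not 0 <= index < d:
        raise ValueError(f"feature index {index} out of range for {d} features")
    keep = [k for k in range(d) if k != index]
    main = traj.spec.main_feature_index
    if main == index:
        new_main = 0
    else:
        new_main = keep.index(main)
    new_spec = dataclasses.replace(
        traj.spec,
        angles=tuple(traj.spec.angles[k] for k in keep),
        rest_pose_angles=tuple(traj.spec.rest_pose_angles[k] for k in keep),
        main_feature_index=new_main,
    )
    return FeatureTrajectory(traj.values[:, keep], traj.timestamps.copy(), new_spec)


# ---------------------------------------------------------------------------
# Built-in exercise specifications

def _sided(template: str, side: str) -> str:
    return template.format(S=side.capitalize())


def builtin_spec(exercise: str, side: str = "none") -> ExerciseSpec:
    """Return the built-in spec for one of the four supported exercises.

    shoulder_abduction and hip_abduction and lunge exist for side left/right;
    sit_to_stand is side-less.  Main feature and rest posture follow the
    clinical exercise descriptions (see package docs).
    """
    if exercise not in EXERCISES:
        raise ValueError(f"unknown exercise: {exercise!r}")
    if exercise == "sit_to_stand":
        if side != "none":
            raise ValueError("sit_to_stand has no side variants")
        angles = (
            # hip angle: torso vs thigh, vertex at the spine base
            AngleDefinition("three-joint", ("SpineShoulder", "SpineBase", "KneeRight"), "theta1"),
            # knee angle
            AngleDefinition("three-joint", ("HipRight", "KneeRight", "AnkleRight"), "theta2"),
        )
        # seated start: torso upright, thigh horizontal, shank vertical
        return ExerciseSpec(exercise, side, angles, 0, (90.0, 90.0))

    if side not in ("left", "right"):
        raise ValueError(f"{exercise} requires side 'left' or 'right'")
    S = side.capitalize()
    other = "Left" if S == "Right" else "Right"
    if exercise == "shoulder_abduction":
        angles = (
            # arm elevation away from the body
            AngleDefinition("segment-vs-vertical", (f"Shoulder{S}", f"Elbow{S}"), "theta1"),
            # elbow angle: is the arm kept stretched?
            AngleDefinition("three-joint", (f"Shoulder{S}", f"Elbow{S}", f"Wrist{S}"), "theta2"),
        )
        return ExerciseSpec(exercise, side, angles, 0, (10.0, 170.0))
    if exercise == "hip_abduction":
        angles = (
            # torso lean (minor feature)
            AngleDefinition("segment-vs-vertical", ("SpineShoulder", "SpineBase"), "theta1"),
            # leg elevation (main feature)
            AngleDefinition("segment-vs-vertical", (f"Hip{S}", f"Knee{S}"), "theta2"),
        )
        return ExerciseSpec(exercise, side, angles, 1, (5.0, 5.0))
    # lunge: front knee, back knee, torso inclination
    angles = (
        AngleDefinition("three-joint", (f"Hip{S}", f"Knee{S}", f"Ankle{S}"), "theta1"),
        AngleDefinition("three-joint", (f"Hip{other}", f"Knee{other}", f"Ankle{other}"), "theta2"),
        AngleDefinition("segment-vs-vertical", ("SpineShoulder", "SpineBase"), "theta3"),
    )
    return ExerciseSpec(exercise, side, angles, 0, (175.0, 175.0, 5.0))


def all_builtin_specs() -> list[ExerciseSpec]:
    """The seven built-in exercise variants (3 sided exercises x 2 + sit-to-stand)."""
    specs = []
    for ex in ("shoulder_abduction", "hip_abduction", "lunge"):
        for side in ("left", "right"):
            specs.append(builtin_spec(ex, side))
    specs.append(builtin_spec("sit_to_stand"))
    return specs


# ---------------------------------------------------------------------------
# Structured-text (YAML) spec files and feature CSV I/O

def spec_to_dict(spec: ExerciseSpec) -> dict:
    return {
        "exercise": spec.exercise,
        "side": spec.side,
        "angles": [
            {"kind": a.kind, "joints": list(a.joints), "label": a.label}
            for a in spec.angles
        ],
        "main_feature_index": spec.main_feature_index,
        "rest_pose_angles": list(spec.rest_pose_angles),
    }


def spec_from_dict(d: dict) -> ExerciseSpec:
    angles = tuple(
        AngleDefinition(a["kind"], tuple(a["joints"]), a.get("label", f"theta{i+1}"))
        for i, a in enumerate(d["angles"])
    )
    return ExerciseSpec(
        d["exercise"],
        d.get("side", "none"),
        angles,
        int(d["main_feature_index"]),
        tuple(float(x) for x in d["rest_pose_angles"]),
    )


def save_spec(spec: ExerciseSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path: str | Path) -> ExerciseSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_features(traj: FeatureTrajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with header timestamp,theta1,theta2[,theta3]."""
    import pandas as pd

    cols = {f"theta{k+1}": traj.values[:, k] for k in range(traj.n_features)}
    pd.DataFrame({"timestamp": traj.timestamps, **cols}).to_csv(
        path, index=False, float_format="%.6f"
    )


def load_features(path: str | Path, spec: ExerciseSpec) -> FeatureTrajectory:
    import pandas as pd

    df = pd.read_csv(path)
    cols = [f"theta{k+1}" for k in range(spec.n_features)]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)}")
    return FeatureTrajectory(df[cols].to_numpy(), df["timestamp"].to_numpy(), spec)
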