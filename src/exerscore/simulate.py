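"""Synthetic exercise sessions.

Generates feature trajectories — and full 25-joint skeleton sessions that
reproduce them through feature extraction — with the structure the scoring
method assumes: a session of n repetitions, each a smooth raised-cosine
excursion of the exercise's angles away from the rest pose, separated by
rest plateaus, sampled at the sensor rate, with additive Gaussian angle
noise emulating depth-camera jitter.

Defaults follow the recording protocol: 5 repetitions of 2 s with 1.5 s
pauses at 30 fps (about 20 s per session), main-feature excursions of
40-90 degrees depending on the exercise.  ``rom_scale`` and ``speed_scale``
degrade the range of motion and the tempo to build graded cohorts of
simulated participants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .features import ExerciseSpec, FeatureTrajectory, builtin_spec
from .skeleton import SkeletonFrame, SkeletonSession

DEFAULT_NOISE_SD = 1.5  # degrees; approximates sensor jitter on joint angles


@dataclass(frozen=True)
class MotionParams:
    """Everything that defines one simulated performance."""

    exercise: str
    side: str
    rest_angles: tuple[float, ...]
    peak_amplitudes: tuple[float, ...]  # signed excursion from rest, degrees
    rep_duration: float = 2.0  # seconds
    pause_duration: float = 1.5  # seconds
    n_reps: int = 5
    frame_rate: float = 30.0
    noise_sd: float = DEFAULT_NOISE_SD
    rom_scale: float = 1.0
    speed_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rep_duration <= 0 or self.frame_rate <= 0:
            raise ValueError("rep_duration and frame_rate must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rom_scale <= 0 or self.speed_scale <= 0:
            raise ValueError("rom_scale and speed_scale must be > 0")
        if len(self.rest_angles) != len(self.peak_amplitudes):
            raise ValueError("rest_angles and peak_amplitudes length mismatch")


#: Default signed main excursions per exercise (degrees from rest).
_DEFAULT_AMPLITUDES = {
    "shoulder_abduction": (80.0, -5.0),   # raise arm to ~90 deg, elbow nearly fixed
    "hip_abduction": (10.0, 80.0),        # slight torso lean, leg raised 80 deg
    "lunge": (-85.0, -85.0, 10.0),        # both knees bend to ~90 deg, torso tips
    "sit_to_stand": (90.0, 90.0),         # hip and knee open from 90 to 180 deg
}


def default_params(spec: ExerciseSpec, **overrides) -> MotionParams:
    """Protocol-default parameters for a built-in exercise spec."""
    amplitudes = _DEFAULT_AMPLITUDES[spec.exercise]
    kwargs = dict(
        exercise=spec.exercise,
        side=spec.side,
        rest_angles=tuple(spec.rest_pose_angles),
        peak_amplitudes=amplitudes,
    )
    kwargs.update(overrides)
    return MotionParams(**kwargs)


def degrade(params: MotionParams, rom_scale: float = 1.0, speed_scale: float = 1.0) -> MotionParams:
    """A copy with degraded range of motion and/or tempo (multiplicative)."""
    if rom_scale <= 0 or speed_scale <= 0:
        raise ValueError("multipliers must be > 0")
    return dataclasses.replace(
        params,
        rom_scale=params.rom_scale * rom_scale,
        speed_scale=params.speed_scale * speed_scale,
    )


def _angle_curves(params: MotionParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free prescribed angle curves plus the time grid."""
    rep = params.rep_duration * params.speed_scale
    pause = params.pause_duration * params.speed_scale
    total = params.n_reps * rep + (params.n_reps + 1) * pause
    n = int(np.floor(total * params.frame_rate)) + 1
    t = np.arange(n) / params.frame_rate

    rest = np.asarray(params.rest_angles, dtype=float)
    amp = np.asarray(params.peak_amplitudes, dtype=float) * params.rom_scale
    values = np.tile(rest, (n, 1))
    for k in range(params.n_reps):
        start = pause + k * (rep + pause)
        inside = (t >= start) & (t <= start + rep)
        phase = (t[inside] - start) / rep
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # raised cosine, peak 1
        values[inside] += np.outer(pulse, amp)
    return values, t


def prescribed_boundaries(params: MotionParams) -> list[tuple[int, int]]:
    """Frame-index [start, end) of each simulated repetition's pulse window.

    Part of the generator's contract: lets scoring bypass automatic
    segmentation, e.g. for degraded performances whose excursions fall
    below any detection threshold.
    """
    rep = params.rep_duration * params.speed_scale
    pause = params.pause_duration * params.speed_scale
    out = []
    for k in range(params.n_reps):
        start = pause + k * (rep + pause)
        i0 = int(np.ceil(start * params.frame_rate))
        i1 = int(np.floor((start + rep) * params.frame_rate)) + 1
        out.append((i0, i1))
    return out


def simulate_feature_trajectory(params: MotionParams, spec: ExerciseSpec) -> FeatureTrajectory:
    """Simulate the angle trajectory directly (no skeleton kinematics).

    Deterministic for a fixed seed.  Angles are clipped to [0, 180] degrees,
    the range of the interior/inclination features the package extracts.
    """
    if spec.n_features != len(params.rest_angles):
        raise ValueError("params feature count does not match spec")
    values, t = _angle_curves(params)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
    return FeatureTrajectory(np.clip(values, 0.0, 180.0), t, spec)


# ---------------------------------------------------------------------------
# Skeleton kinematics

# Neutral standing stick figure (meters, y up; limb lengths are arbitrary
# constants — the extracted features are invariant to them).
_L_UPPER_ARM = 0.30
_L_FOREARM = 0.26
_L_TORSO = 0.45
_L_THIGH = 0.45
_L_SHANK = 0.40

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _neutral_skeleton() -> dict[str, np.ndarray]:
    sb = np.array([0.0, 1.00, 0.0])
    ss = sb + _L_TORSO * _Y
    joints = {
        "SpineBase": sb,
        "SpineMid": sb + 0.5 * _L_TORSO * _Y,
        "SpineShoulder": ss,
        "Neck": ss + np.array([0.0, 0.08, 0.0]),
        "Head": ss + np.array([0.0, 0.22, 0.0]),
    }
    for side, sx in (("Left", -1.0), ("Right", 1.0)):
        shoulder = ss + np.array([0.20 * sx, -0.03, 0.0])
        elbow = shoulder + _L_UPPER_ARM * -_Y
        wrist = elbow + _L_FOREARM * -_Y
        hip = sb + np.array([0.09 * sx, 0.0, 0.0])
        knee = hip + _L_THIGH * -_Y
        ankle = knee + _L_SHANK * -_Y
        joints.update({
            f"Shoulder{side}": shoulder,
            f"Elbow{side}": elbow,
            f"Wrist{side}": wrist,
            f"Hand{side}": wrist + np.array([0.0, -0.07, 0.02]),
            f"HandTip{side}": wrist + np.array([0.0, -0.12, 0.03]),
            f"Thumb{side}": wrist + np.array([0.03 * sx, -0.05, 0.03]),
            f"Hip{side}": hip,
            f"Knee{side}": knee,
            f"Ankle{side}": ankle,
            f"Foot{side}": ankle + np.array([0.0, -0.03, 0.12]),
        })
    return joints


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _incline_dir(angle_deg: float, horizontal: np.ndarray) -> np.ndarray:
    """Unit vector at ``angle_deg`` from the downward vertical, tipping
    toward ``horizontal``."""
    a = np.radians(angle_deg)
    return np.sin(a) * horizontal + np.cos(a) * np.array([0.0, -1.0, 0.0])


def _place_by_angle(vertex, ref_point, angle_deg, length, axis) -> np.ndarray:
    """Point at ``length`` from ``vertex`` such that the interior angle at
    ``vertex`` between vertex->ref_point and vertex->result is ``angle_deg``
    exactly; the new segment lies in the plane spanned by vertex->ref_point
    and the rotation ``axis``'s orthogonal complement."""
    u = _unit(np.asarray(ref_point, float) - np.asarray(vertex, float))
    a = np.asarray(axis, float)
    a = a - np.dot(a, u) * u
    if np.linalg.norm(a) < 1e-12:
        raise ValueError("rotation axis parallel to reference segment")
    a = _unit(a)
    ang = np.radians(angle_deg)
    s = np.cos(ang) * u + np.sin(ang) * np.cross(a, u)
    return np.asarray(vertex, float) + length * s


def _clip180(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 180.0)


def simulate_skeleton_session(params: MotionParams, spec: ExerciseSpec) -> SkeletonSession:
    """Simulate a full 25-joint session whose extracted features reproduce
    :func:`simulate_feature_trajectory` for the same parameters.

    Only the joints involved in the exercise move; the rest of the stick
    figure stays in the neutral standing pose.  Supported for the built-in
    exercise specs.
    """
    traj = simulate_feature_trajectory(params, spec)
    angles = _clip180(traj.values)
    base = _neutral_skeleton()
    placer = _PLACERS.get(spec.exercise)
    if placer is None:
        raise ValueError(f"unsupported exercise for skeleton simulation: {spec.exercise}")

    frames = []
    for i, t in enumerate(traj.timestamps):
        joints = {k: v.copy() for k, v in base.items()}
        placer(joints, angles[i], spec)
        frames.append(SkeletonFrame(float(t), joints))
    return SkeletonSession(spec.exercise, spec.side, frames, params.frame_rate)


def _place_shoulder_abduction(joints, ang, spec: ExerciseSpec) -> None:
    side = spec.side.capitalize()
    sx = 1.0 if side == "Right" else -1.0
    theta1, theta2 = ang
    shoulder = joints[f"Shoulder{side}"]
    upper = _incline_dir(theta1, sx * _X)
    elbow = shoulder + _L_UPPER_ARM * upper
    wrist = _place_by_angle(elbow, shoulder, theta2, _L_FOREARM, _Z)
    joints[f"Elbow{side}"] = elbow
    joints[f"Wrist{side}"] = wrist
    hand_dir = _unit(wrist - elbow)
    joints[f"Hand{side}"] = wrist + 0.07 * hand_dir
    joints[f"HandTip{side}"] = wrist + 0.12 * hand_dir
    joints[f"Thumb{side}"] = wrist + 0.05 * hand_dir + 0.03 * _Z


def _lean_torso(joints, angle_deg: float, horizontal: np.ndarray) -> None:
    # SpineShoulder placed so the SpineShoulder->SpineBase segment makes
    # ``angle_deg`` with the downward vertical; SpineBase stays fixed.
    sb = joints["SpineBase"]
    down = _incline_dir(angle_deg, horizontal)
    ss = sb - _L_TORSO * down
    joints["SpineShoulder"] = ss
    joints["SpineMid"] = sb - 0.5 * _L_TORSO * down
    joints["Neck"] = ss + np.array([0.0, 0.08, 0.0])
    joints["Head"] = ss + np.array([0.0, 0.22, 0.0])


def _place_hip_abduction(joints, ang, spec: ExerciseSpec) -> None:
    side = spec.side.capitalize()
    sx = 1.0 if side == "Right" else -1.0
    theta1, theta2 = ang
    _lean_torso(joints, theta1, -sx * _X)  # lean away from the lifting leg
    hip = joints[f"Hip{side}"]
    leg = _incline_dir(theta2, sx * _X)
    knee = hip + _L_THIGH * leg
    ankle = knee + _L_SHANK * leg  # straight leg
    joints[f"Knee{side}"] = knee
    joints[f"Ankle{side}"] = ankle
    joints[f"Foot{side}"] = ankle + np.array([0.0, -0.03, 0.12])


def _place_lunge(joints, ang, spec: ExerciseSpec) -> None:
    front = spec.side.capitalize()
    back = "Left" if front == "Right" else "Right"
    theta1, theta2, theta3 = ang
    _lean_torso(joints, theta3, _Z)  # slight forward tip
    for leg_side, knee_angle, fwd in ((front, theta1, 1.0), (back, theta2, -1.0)):
        hip = joints[f"Hip{leg_side}"]
        beta = 0.5 * (180.0 - knee_angle)
        thigh = _incline_dir(beta, fwd * _Z)
        knee = hip + _L_THIGH * thigh
        ankle = _place_by_angle(knee, hip, knee_angle, _L_SHANK, _X)
        joints[f"Knee{leg_side}"] = knee
        joints[f"Ankle{leg_side}"] = ankle
        joints[f"Foot{leg_side}"] = ankle + np.array([0.0, -0.03, 0.12 * fwd])


def _place_sit_to_stand(joints, ang, spec: ExerciseSpec) -> None:
    theta1, theta2 = ang
    sb = joints["SpineBase"]
    # Hip angle: vertex SpineBase, between SpineShoulder (upright torso) and
    # the knee; the thigh tips forward (+z) as the angle closes toward 90.
    knee_r = _place_by_angle(sb, joints["SpineShoulder"], theta1, _L_THIGH, _X)
    thigh_vec = knee_r - joints["HipRight"]
    for side in ("Right", "Left"):
        hip = joints[f"Hip{side}"]
        knee = hip + thigh_vec
        ankle = _place_by_angle(knee, hip, theta2, _L_SHANK, _X)
        joints[f"Knee{side}"] = knee
        joints[f"Ankle{side}"] = ankle
        joints[f"Foot{side}"] = ankle + np.array([0.0, -0.03, 0.12])


_PLACERS = {
    "shoulder_abduction": _place_shoulder_abduction,
    "hip_abduction": _place_hip_abduction,
    "lunge": _place_lunge,
    "sit_to_stand": _place_sit_to_stand,
}


def simulate_cohort(
    spec: ExerciseSpec,
    rom_scales,
    base_params: MotionParams | None = None,
    seed: int = 0,
) -> dict[str, FeatureTrajectory]:
    """Feature trajectories for a graded cohort of simulated participants,
    one per range-of-motion scale, with distinct noise realizations."""
    if base_params is None:
        base_params = default_params(spec, seed=seed)
    cohort = {}
    for k, s in enumerate(rom_scales):
        p = degrade(base_params, rom_scale=s)
        p = dataclasses.replace(p, seed=base_params.seed + 1000 + k)
        cohort[f"rom_{s:g}"] = simulate_feature_trajectory(p, spec)
    return cohort
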