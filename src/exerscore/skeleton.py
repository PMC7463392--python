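"""Skeleton session container, joint vocabulary, and tabular I/O.

A session is an ordered sequence of timestamped frames, each mapping joint
names to 3D positions in meters.  The joint vocabulary is the 25-joint
skeleton exposed by depth-camera SDKs of the Kinect-V2 family.  Coordinates
are camera-space meters (right-handed, y-up by convention); since all
downstream features are relative joint angles, the global frame never
affects scores and is documented rather than enforced.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The 25 admissible skeleton joint labels.
KINECT_JOINTS: tuple[str, ...] = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

_JOINT_SET = frozenset(KINECT_JOINTS)

#: Nominal sensor frame rate in frames per second.
DEFAULT_FRAME_RATE = 30.0


def validate_joint(name: str) -> str:
    """Return ``name`` if it is one of the 25 admissible joint labels."""
    if name not in _JOINT_SET:
        raise ValueError(f"unknown joint label: {name!r}")
    return name


@dataclass
class SkeletonFrame:
    """One timestamped sample of joint positions (meters)."""

    timestamp: float
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp: {self.timestamp}")
        clean: dict[str, np.ndarray] = {}
        for joint, pos in self.positions.items():
            validate_joint(joint)
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"position of {joint} is not a 3-vector")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinates for joint {joint}")
            clean[joint] = arr
        self.positions = clean


@dataclass
class SkeletonSession:
    """An ordered, validated recording of one exercise execution.

    Missing optional joints (hands, thumbs) are tolerated here; whether the
    joints required by an exercise are present is checked at feature
    extraction time, so a session can be stored generically.
    """

    exercise: str
    side: str
    frames: list[SkeletonFrame]
    nominal_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be > 0")
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("non-monotonic timestamps")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def common_joints(self) -> set[str]:
        """Joints present in every frame."""
        joints = set(KINECT_JOINTS)
        for f in self.frames:
            joints &= f.positions.keys()
        return joints


_CSV_COLUMNS = ["frame", "timestamp", "joint", "x", "y", "z"]


def read_session(
    path: str | Path,
    exercise: str,
    side: str = "none",
    nominal_rate: float = DEFAULT_FRAME_RATE,
) -> SkeletonSession:
    """Read a skeleton session from the tabular CSV format.

    The format has one row per joint per frame with header
    ``frame,timestamp,joint,x,y,z``; coordinates in meters.  Timestamps are
    normalized so the session starts at 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed skeleton CSV, missing columns: {sorted(missing)}")
    for joint in df["joint"].unique():
        validate_joint(str(joint))

    frames: list[SkeletonFrame] = []
    grouped = df.groupby("frame", sort=True)
    for _, g in grouped:
        ts = g["timestamp"].unique()
        if len(ts) != 1:
            raise ValueError("inconsistent timestamps within one frame")
        positions = {
            str(row.joint): np.array([row.x, row.y, row.z], dtype=float)
            for row in g.itertuples()
        }
        frames.append(SkeletonFrame(float(ts[0]), positions))
    frames.sort(key=lambda f: f.timestamp)
    if frames:
        t0 = frames[0].timestamp
        frames = [dataclasses.replace(f, timestamp=f.timestamp - t0) for f in frames]
    return SkeletonSession(exercise, side, frames, nominal_rate)


def write_session(session: SkeletonSession, path: str | Path) -> None:
    """Write a session to the tabular CSV format (9 decimal places)."""
    if not session.frames:
        raise ValueError("empty session")
    records = []
    for i, frame in enumerate(session.frames):
        for joint, pos in frame.positions.items():
            records.append((i, frame.timestamp, joint, pos[0], pos[1], pos[2]))
    df = pd.DataFrame.from_records(records, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def resample_session(session: SkeletonSession, rate: float) -> SkeletonSession:
    """Resample a session onto a uniform time grid at ``rate`` fps.

    Positions are linearly interpolated per coordinate over the joints
    present in every frame.  Supports comparing recordings captured at
    different rates.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if len(session.frames) < 2:
        raise ValueError("resampling requires at least 2 frames")
    joints = sorted(session.common_joints())
    old_t = session.timestamps
    span = old_t[-1] - old_t[0]
    n_new = int(np.floor(span * rate)) + 1
    new_t = old_t[0] + np.arange(n_new) / rate

    stacked = {
        j: np.stack([f.positions[j] for f in session.frames]) for j in joints
    }
    frames = []
    for k, t in enumerate(new_t):
        positions = {
            j: np.array([np.interp(t, old_t, stacked[j][:, c]) for c in range(3)])
            for j in joints
        }
        frames.append(SkeletonFrame(float(t), positions))
    return SkeletonSession(session.exercise, session.side, frames, rate)
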