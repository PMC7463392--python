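"""Repetition segmentation and the keep-middle selection rule.

Sessions contain at least five repetitions separated by short rest pauses.
Repetitions are located on the dominant feature by prominence-based peak
detection after light smoothing; each repetition spans from one return to
the rest band, through exactly one prominent excursion, back to rest.  The
first and last detected repetitions are discarded before scoring, since they
tend to include the startup and wind-down of the recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .features import FeatureTrajectory

log = logging.getLogger(__name__)

#: Minimum peak prominence (degrees) for an excursion to count as a repetition.
DEFAULT_MIN_PROMINENCE = 20.0
#: Half-width (degrees) of the band around the rest angle treated as "at rest".
DEFAULT_REST_BAND = 10.0
_SMOOTH_WINDOW = 5


@dataclass
class Repetition:
    """One contiguous slice [start, end) of a feature trajectory."""

    start_index: int
    end_index: int
    values: FeatureTrajectory

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("repetition must have start < end")

    def __len__(self) -> int:
        return self.end_index - self.start_index

    @property
    def matrix(self) -> np.ndarray:
        return self.values.values


def _slice(traj: FeatureTrajectory, start: int, end: int) -> Repetition:
    start, end = int(start), int(end)
    sub = FeatureTrajectory(
        traj.values[start:end].copy(), traj.timestamps[start:end].copy(), traj.spec
    )
    return Repetition(start, end, sub)


def segment_repetitions(
    traj: FeatureTrajectory,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    rest_band: float = DEFAULT_REST_BAND,
) -> list[Repetition]:
    """Split a trajectory into repetitions around prominent main-feature excursions.

    Works on the signed deviation of the main feature from its rest angle;
    the dominant polarity is used, so exercises whose excursion is a dip
    below rest (e.g. sit-to-stand performed from standing, or knee flexion
    in a lunge) are handled the same way as raises.  A flat signal yields an
    empty list rather than an error.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    rest = traj.spec.rest_pose_angles[traj.spec.main_feature_index]
    dev = traj.main - rest
    smooth = uniform_filter1d(dev, size=_SMOOTH_WINDOW, mode="nearest")
    if abs(smooth.min()) > abs(smooth.max()):
        smooth = -smooth  # dip-shaped excursions

    peaks, _ = find_peaks(smooth, prominence=min_prominence)
    if len(peaks) == 0:
        return []

    # Boundary for each peak: nearest sample inside the rest band on each side,
    # constrained not to cross the valley separating adjacent peaks.
    valleys = [int(np.argmin(smooth[p0:p1])) + p0 for p0, p1 in zip(peaks[:-1], peaks[1:])]
    reps: list[Repetition] = []
    n = len(smooth)
    for i, p in enumerate(peaks):
        lo_limit = valleys[i - 1] if i > 0 else 0
        hi_limit = valleys[i] if i < len(valleys) else n - 1
        at_rest = smooth <= rest_band
        start = p
        while start > lo_limit and not at_rest[start]:
            start -= 1
        end = p
        while end < hi_limit and not at_rest[end]:
            end += 1
        reps.append(_slice(traj, start, end + 1))
    return reps


def select_scoring_repetitions(reps: list[Repetition]) -> list[Repetition]:
    """Drop the first and the last repetition; the middle ones are scored.

    With the protocol's five repetitions this retains three.
    """
    if len(reps) < 3:
        raise ValueError(
            f"insufficient repetitions: need at least 3, got {len(reps)}"
        )
    if len(reps) < 5:
        log.warning("only %d repetitions detected (protocol asks for >= 5)", len(reps))
    return reps[1:-1]
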