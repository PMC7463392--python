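"""Multivariate dynamic time warping and the DTW similarity score.

DTW aligns two feature trajectories under monotone step constraints
{(1,0),(0,1),(1,1)} with unit step weights and local cost equal to the
Euclidean distance between feature rows, and returns the minimal accumulated
cost D.  D = 0 only for identical sequences; the upper bound D_u is anchored
to the worst conceivable performance — not moving at all, i.e. the constant
rest-pose trajectory — giving the percentage score

    S_D = 100 * (1 - D / D_u),  clamped to [0, 100].

Multiplying D_u by a sensitivity factor > 1 smooths scores (smaller
differences between participants); a factor < 1 sharpens them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .features import ExerciseSpec, FeatureTrajectory
from .scores import SimilarityScore, clamp_score

log = logging.getLogger(__name__)


@dataclass
class DtwResult:
    """Accumulated alignment cost and (optionally) the warping path."""

    distance: float
    path: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("DTW distance must be non-negative")


@dataclass
class ScoreBounds:
    """Worst-performance normalizer for DTW scores: D in [0, D_u]."""

    d_upper: float
    d_lower: float = 0.0
    sensitivity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.d_upper <= 0:
            raise ValueError("degenerate bound: D_u must be > 0")
        if self.sensitivity_factor <= 0:
            raise ValueError("sensitivity_factor must be > 0")

    @property
    def effective_upper(self) -> float:
        return self.d_upper * self.sensitivity_factor

    def scaled(self, factor: float) -> "ScoreBounds":
        """The same bound with the sensitivity factor multiplied by ``factor``."""
        return ScoreBounds(self.d_upper, self.d_lower, self.sensitivity_factor * factor)


def _as_matrix(seq) -> np.ndarray:
    if isinstance(seq, FeatureTrajectory):
        return seq.values
    if hasattr(seq, "matrix"):  # Repetition
        return seq.matrix
    arr = np.asarray(seq, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def dtw_distance(seq_a, seq_b, return_path: bool = False) -> DtwResult:
    """Classic dynamic-programming DTW with Euclidean local cost.

    Accepts feature matrices (frames x features), 1-D arrays, feature
    trajectories, or repetitions; both inputs must have the same feature
    count.
    """
    a = _as_matrix(seq_a)
    b = _as_matrix(seq_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty sequence")
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature-count mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    cost = cdist(a, b)
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        c = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    distance = float(acc[n, m])

    path = None
    if return_path:
        path = [(n - 1, m - 1)]
        i, j = n, m
        while (i, j) != (1, 1):
            steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
            i, j = min(
                (s for s in steps if s[0] >= 1 and s[1] >= 1),
                key=lambda s: acc[s],
            )
            path.append((i - 1, j - 1))
        path.reverse()
    return DtwResult(distance, path)


def worst_trajectory(spec: ExerciseSpec, length: int) -> np.ndarray:
    """The constant rest-pose feature matrix: 'not moving' for ``length`` frames."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return np.tile(np.asarray(spec.rest_pose_angles, dtype=float), (length, 1))


def dtw_upper_bound(
    reference_reps,
    spec: ExerciseSpec,
    aggregate: str = "mean",
    sensitivity_factor: float = 1.0,
) -> ScoreBounds:
    """Worst-performance upper bound D_u from the reference repetitions.

    Each reference repetition is compared against a constant rest-pose
    trajectory of its own length; per-repetition distances are aggregated
    with ``mean`` (default) or ``max``.
    """
    reps = [_as_matrix(r) for r in reference_reps]
    if not reps:
        raise ValueError("empty reference set")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    dists = [
        dtw_distance(r, worst_trajectory(spec, r.shape[0])).distance for r in reps
    ]
    d_u = float(np.mean(dists) if aggregate == "mean" else np.max(dists))
    if d_u <= 0:
        raise ValueError(
            "degenerate bound: reference is indistinguishable from the "
            "worst (rest) trajectory"
        )
    return ScoreBounds(d_u, 0.0, sensitivity_factor)


def dtw_similarity(distance: float, bounds: ScoreBounds) -> SimilarityScore:
    """Convert one DTW distance to a percentage score against the bounds."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    raw = 100.0 * (1.0 - distance / bounds.effective_upper)
    if raw < 0:
        log.info(
            "DTW distance %.3f exceeds effective bound %.3f; score clamped to 0",
            distance, bounds.effective_upper,
        )
    return SimilarityScore(clamp_score(raw), "dtw", [raw])


def participant_dtw_score(
    participant_reps, reference_reps, bounds: ScoreBounds
) -> SimilarityScore:
    """All-pairs DTW score: every participant repetition against every
    reference repetition (3 x 3 = 9 values under the standard protocol),
    averaged.  Per-pair values are retained unclamped for error bars; the
    final average is clamped to [0, 100].
    """
    p = [_as_matrix(r) for r in participant_reps]
    r = [_as_matrix(x) for x in reference_reps]
    if not p or not r:
        raise ValueError("empty repetition list")
    per_pair = []
    for pi in p:
        for rj in r:
            d = dtw_distance(pi, rj).distance
            per_pair.append(100.0 * (1.0 - d / bounds.effective_upper))
    return SimilarityScore(clamp_score(float(np.mean(per_pair))), "dtw", per_pair)
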