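"""End-to-end assessment runs and report generation.

One run covers a set of exercises: for each exercise the reference
trajectory is segmented, the middle repetitions are kept, the DTW bound
D_u and the reference HMM (with its bound L_l) are derived from them, and
every participant is scored — the all-pairs DTW average (9 values under
the standard 3x3 protocol) and the per-repetition HMM average (3 values).
The report also carries each participant's across-exercise average built
from all raw pairwise DTW values (9 per exercise).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dtw as dtw_mod
from . import hmm as hmm_mod
from .features import ExerciseSpec, FeatureTrajectory, extract_features
from .scores import SimilarityScore
from .segmentation import (
    DEFAULT_MIN_PROMINENCE,
    DEFAULT_REST_BAND,
    Repetition,
    segment_repetitions,
    select_scoring_repetitions,
)
from .skeleton import SkeletonSession

log = logging.getLogger(__name__)


@dataclass
class ExerciseTask:
    """One exercise to assess: a reference and any number of participants.

    Inputs may be skeleton sessions or pre-extracted feature trajectories.
    ``participant_boundaries`` optionally bypasses automatic segmentation
    with explicit per-participant [start, end) frame-index pairs.
    """

    spec: ExerciseSpec
    reference: SkeletonSession | FeatureTrajectory
    participants: dict[str, SkeletonSession | FeatureTrajectory]
    participant_boundaries: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class AssessmentConfig:
    tasks: list[ExerciseTask]
    min_prominence: float = DEFAULT_MIN_PROMINENCE
    rest_band: float = DEFAULT_REST_BAND
    n_states: int = hmm_mod.DEFAULT_N_STATES
    seed: int = 0
    quantizer_centers: list[list[float]] | None = None  # per-feature; None = default grid
    sensitivity_dtw: float = 1.0
    sensitivity_hmm: float = 1.0
    bound_aggregation: str = "mean"


@dataclass
class ExerciseResult:
    """Scores of one participant on one exercise."""

    participant: str
    exercise: str
    side: str
    s_d: float
    s_h: float
    difference: float  # S_H - S_D
    dtw_per_pair: list[float]
    hmm_per_rep: list[float]
    s_d_sem: float
    s_h_sem: float
    d_upper: float
    l_lower: float
    n_repetitions: int


@dataclass
class AssessmentReport:
    rows: list[ExerciseResult]
    overall: dict[str, dict[str, float]]  # participant -> aggregate scores
    metadata: dict

    def participants(self) -> list[str]:
        return sorted({r.participant for r in self.rows})


def _as_trajectory(obj, spec: ExerciseSpec) -> FeatureTrajectory:
    if isinstance(obj, FeatureTrajectory):
        return obj
    if isinstance(obj, SkeletonSession):
        return extract_features(obj, spec)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a trajectory")


def _explicit_reps(traj: FeatureTrajectory, boundaries) -> list[Repetition]:
    reps = []
    for start, end in boundaries:
        sub = FeatureTrajectory(
            traj.values[start:end].copy(), traj.timestamps[start:end].copy(), traj.spec
        )
        reps.append(Repetition(start, end, sub))
    return reps


def _fallback_slices(traj: FeatureTrajectory, n: int) -> list[Repetition]:
    """Split a trajectory into ``n`` equal slices.

    Used when no repetitions are detectable (e.g. a participant who never
    leaves the rest pose must still be scored, and will score near 0)."""
    edges = np.linspace(0, len(traj), n + 1).astype(int)
    return _explicit_reps(traj, list(zip(edges[:-1], edges[1:])))


def _scoring_reps(
    traj: FeatureTrajectory,
    config: AssessmentConfig,
    boundaries=None,
    n_fallback: int = 3,
    label: str = "",
) -> list[Repetition]:
    if boundaries:
        return _explicit_reps(traj, boundaries)
    reps = segment_repetitions(traj, config.min_prominence, config.rest_band)
    if len(reps) >= 3:
        return select_scoring_repetitions(reps)
    log.warning(
        "%s: only %d repetitions detected; scoring %d equal slices instead",
        label or "trajectory", len(reps), n_fallback,
    )
    return _fallback_slices(traj, n_fallback)


def score_exercise(
    task: ExerciseTask, config: AssessmentConfig
) -> tuple[list[ExerciseResult], dict]:
    """Score every participant of one task; returns rows plus exercise metadata."""
    spec = task.spec
    ref_traj = _as_trajectory(task.reference, spec)
    ref_reps = select_scoring_repetitions(
        segment_repetitions(ref_traj, config.min_prominence, config.rest_band)
    )

    bounds_d = dtw_mod.dtw_upper_bound(
        ref_reps, spec, aggregate=config.bound_aggregation,
        sensitivity_factor=config.sensitivity_dtw,
    )
    if config.quantizer_centers is not None:
        quantizer = hmm_mod.build_quantizer(config.quantizer_centers)
    else:
        quantizer = hmm_mod.default_quantizer(spec)
    ref_syms = [hmm_mod.quantize(r, quantizer) for r in ref_reps]
    model = hmm_mod.train_reference_hmm(
        ref_syms, n_states=config.n_states, seed=config.seed,
        n_symbols=quantizer.codebook_size,
    )
    mean_len = int(round(np.mean([len(r) for r in ref_reps])))
    bounds_h = hmm_mod.hmm_lower_bound(
        spec, quantizer, model, mean_len, sensitivity_factor=config.sensitivity_hmm
    )

    rows = []
    for name, perf in task.participants.items():
        traj = _as_trajectory(perf, spec)
        reps = _scoring_reps(
            traj, config,
            boundaries=task.participant_boundaries.get(name),
            n_fallback=len(ref_reps),
            label=f"{name}/{spec.name}",
        )
        s_d = dtw_mod.participant_dtw_score(reps, ref_reps, bounds_d)
        syms = [hmm_mod.quantize(r, quantizer) for r in reps]
        s_h = hmm_mod.participant_hmm_score(syms, model, bounds_h)
        rows.append(ExerciseResult(
            participant=name,
            exercise=spec.exercise,
            side=spec.side,
            s_d=s_d.value,
            s_h=s_h.value,
            difference=s_h.value - s_d.value,
            dtw_per_pair=list(s_d.per_pair_values),
            hmm_per_rep=list(s_h.per_pair_values),
            s_d_sem=s_d.standard_error,
            s_h_sem=s_h.standard_error,
            d_upper=bounds_d.d_upper,
            l_lower=bounds_h.l_lower,
            n_repetitions=len(reps),
        ))
    meta = {
        "exercise": spec.name,
        "d_upper": bounds_d.d_upper,
        "l_lower": bounds_h.l_lower,
        "n_reference_reps": len(ref_reps),
    }
    log.info("exercise %s: D_u=%.3f, L_l=%.4f, %d reference reps",
             spec.name, bounds_d.d_upper, bounds_h.l_lower, len(ref_reps))
    return rows, meta


def run_assessment(config: AssessmentConfig) -> AssessmentReport:
    """Assess every participant on every exercise and aggregate.

    The across-exercise average per participant pools all raw pairwise DTW
    values (9 per exercise) and all raw per-repetition HMM values (3 per
    exercise), then clamps the pooled means to [0, 100].
    """
    rows: list[ExerciseResult] = []
    per_exercise_meta = []
    for task in config.tasks:
        task_rows, meta = score_exercise(task, config)
        rows.extend(task_rows)
        per_exercise_meta.append(meta)

    overall: dict[str, dict[str, float]] = {}
    for name in sorted({r.participant for r in rows}):
        d_raw = [v for r in rows if r.participant == name for v in r.dtw_per_pair]
        h_raw = [v for r in rows if r.participant == name for v in r.hmm_per_rep]
        overall[name] = {
            "s_d_overall": float(np.clip(np.mean(d_raw), 0.0, 100.0)),
            "s_h_overall": float(np.clip(np.mean(h_raw), 0.0, 100.0)),
            "n_dtw_values": len(d_raw),
            "n_hmm_values": len(h_raw),
        }
    metadata = {
        "seed": config.seed,
        "n_states": config.n_states,
        "sensitivity_dtw": config.sensitivity_dtw,
        "sensitivity_hmm": config.sensitivity_hmm,
        "bound_aggregation": config.bound_aggregation,
        "exercises": per_exercise_meta,
    }
    return AssessmentReport(rows, overall, metadata)


def compare_sides(report: AssessmentReport) -> dict[str, dict[str, float]]:
    """Paired left/right score comparison per exercise and method.

    Returns, per sided exercise, the mean left and right scores over
    participants and their mean difference (left - right), for both
    methods.  No hypothesis testing is performed; the raw values in the
    report support running tests externally.
    """
    sided = sorted({r.exercise for r in report.rows if r.side in ("left", "right")})
    out: dict[str, dict[str, float]] = {}
    for ex in sided:
        by_side = {
            side: {r.participant: r for r in report.rows if r.exercise == ex and r.side == side}
            for side in ("left", "right")
        }
        shared = sorted(by_side["left"].keys() & by_side["right"].keys())
        if not shared:
            continue
        entry = {}
        for method, attr in (("s_d", "s_d"), ("s_h", "s_h")):
            left = np.array([getattr(by_side["left"][p], attr) for p in shared])
            right = np.array([getattr(by_side["right"][p], attr) for p in shared])
            entry[f"{method}_left_mean"] = float(left.mean())
            entry[f"{method}_right_mean"] = float(right.mean())
            entry[f"{method}_mean_difference"] = float((left - right).mean())
        entry["n_participants"] = len(shared)
        out[ex] = entry
    if not out:
        raise ValueError("report contains no paired left/right exercises")
    return out


# ---------------------------------------------------------------------------
# Serialization

def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "rows": [dataclasses.asdict(r) for r in report.rows],
        "overall": report.overall,
        "metadata": report.metadata,
    }


def report_from_dict(d: dict) -> AssessmentReport:
    rows = [ExerciseResult(**r) for r in d["rows"]]
    return AssessmentReport(rows, d["overall"], d["metadata"])


def write_report(report: AssessmentReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report: lossless JSON, or CSV with one row per
    participant x exercise x method."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=1))
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([
                "participant", "exercise", "side", "method", "score",
                "standard_error", "difference_sh_minus_sd", "n_repetitions", "raw_values",
            ])
            for r in report.rows:
                for method, score, sem, raw in (
                    ("dtw", r.s_d, r.s_d_sem, r.dtw_per_pair),
                    ("hmm", r.s_h, r.s_h_sem, r.hmm_per_rep),
                ):
                    writer.writerow([
                        r.participant, r.exercise, r.side, method,
                        f"{score:.6f}", f"{sem:.6f}", f"{r.difference:.6f}",
                        r.n_repetitions, ";".join(f"{v:.6f}" for v in raw),
                    ])
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path) -> AssessmentReport:
    return report_from_dict(json.loads(Path(path).read_text()))
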