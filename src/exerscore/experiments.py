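"""Reusable simulated study protocols.

These functions wrap the library into the small in-silico experiments the
package documents: a reference performance is simulated, a cohort of
degraded participants is scored against it, and the resulting score tables
are returned for inspection.  They are used by the test suite, by the
results-reproduction script, and directly from the REPL.

The range-of-motion (ROM) cohort protocol runs on shoulder abduction by
default: its peak angles fall well inside the default quantization
clusters at every scale, so the ROM effect on the HMM score is not
confounded by the (separately documented) cluster-boundary sensitivity of
the quantization step.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import dtw as dtw_mod
from . import hmm as hmm_mod
from .features import ExerciseSpec, FeatureTrajectory, builtin_spec, drop_feature
from .pipeline import _explicit_reps
from .segmentation import Repetition, segment_repetitions, select_scoring_repetitions
from .simulate import default_params, degrade, prescribed_boundaries, simulate_feature_trajectory

ROM_SCALES = (1.0, 0.8, 0.6, 0.4, 0.2)


@dataclasses.dataclass
class ReferenceSetup:
    """A trained scoring setup derived from one simulated reference."""

    spec: ExerciseSpec
    reference_reps: list[Repetition]
    dtw_bounds: dtw_mod.ScoreBounds
    quantizer: hmm_mod.Quantizer
    model: hmm_mod.DiscreteHMM
    hmm_bounds: hmm_mod.HmmScoreBounds

    def score(self, reps, sensitivity_dtw: float = 1.0, sensitivity_hmm: float = 1.0):
        """(S_D, S_H) of a list of participant repetitions."""
        s_d = dtw_mod.participant_dtw_score(
            reps, self.reference_reps, self.dtw_bounds.scaled(sensitivity_dtw)
        )
        syms = [hmm_mod.quantize(r, self.quantizer) for r in reps]
        s_h = hmm_mod.participant_hmm_score(
            syms, self.model, self.hmm_bounds.scaled(sensitivity_hmm)
        )
        return s_d, s_h


def build_reference_setup(
    spec: ExerciseSpec, seed: int, n_states: int = hmm_mod.DEFAULT_N_STATES
) -> ReferenceSetup:
    """Simulate a reference session and derive bounds, quantizer and model."""
    params = default_params(spec, seed=seed)
    ref = simulate_feature_trajectory(params, spec)
    ref_reps = select_scoring_repetitions(segment_repetitions(ref))
    dtw_bounds = dtw_mod.dtw_upper_bound(ref_reps, spec)
    quantizer = hmm_mod.default_quantizer(spec)
    syms = [hmm_mod.quantize(r, quantizer) for r in ref_reps]
    model = hmm_mod.train_reference_hmm(
        syms, n_states=n_states, seed=seed + 1, n_symbols=quantizer.codebook_size
    )
    mean_len = int(round(np.mean([len(r) for r in ref_reps])))
    hmm_bounds = hmm_mod.hmm_lower_bound(spec, quantizer, model, mean_len)
    return ReferenceSetup(spec, ref_reps, dtw_bounds, quantizer, model, hmm_bounds)


def degraded_participant_reps(
    spec: ExerciseSpec, seed: int, rom_scale: float = 1.0, speed_scale: float = 1.0
) -> list[Repetition]:
    """Middle repetitions of one degraded simulated participant.

    Repetition boundaries come from the generator's prescribed pulse
    windows, so participants whose excursions are too small for automatic
    detection are still scored on their actual repetitions.
    """
    params = degrade(default_params(spec, seed=seed), rom_scale, speed_scale)
    traj = simulate_feature_trajectory(params, spec)
    boundaries = prescribed_boundaries(params)[1:-1]  # keep-middle rule
    return _explicit_reps(traj, boundaries)


def rom_cohort_scores(
    seed: int,
    spec: ExerciseSpec | None = None,
    scales=ROM_SCALES,
    n_replicates: int = 3,
    sensitivity_dtw: float = 1.0,
    sensitivity_hmm: float = 1.0,
) -> dict[float, dict[str, float]]:
    """Mean scores of a graded ROM cohort against a full-ROM reference.

    For each scale, ``n_replicates`` participants (distinct noise
    realizations) are simulated and their scores averaged.
    """
    spec = spec or builtin_spec("shoulder_abduction", "left")
    setup = build_reference_setup(spec, seed)
    out: dict[float, dict[str, float]] = {}
    for k, s in enumerate(scales):
        sd, sh = [], []
        for j in range(n_replicates):
            reps = degraded_participant_reps(spec, seed + 100 + j, rom_scale=s)
            a, b = setup.score(reps, sensitivity_dtw, sensitivity_hmm)
            sd.append(a.value)
            sh.append(b.value)
        out[s] = {"s_d": float(np.mean(sd)), "s_h": float(np.mean(sh))}
    return out


def sensitivity_scaling_table(
    seed: int, factors=(0.5, 1.0, 2.0), scales=ROM_SCALES
) -> dict[float, dict[float, dict[str, float]]]:
    """Cohort scores under scaled worst-performance bounds (factor x D_u,
    factor x |L_l|): larger factors smooth the scores together, smaller
    factors sharpen their differences."""
    spec = builtin_spec("shoulder_abduction", "left")
    setup = build_reference_setup(spec, seed)
    cohort = {s: degraded_participant_reps(spec, seed + 100, rom_scale=s) for s in scales}
    out: dict[float, dict[float, dict[str, float]]] = {}
    for f in factors:
        out[f] = {}
        for s, reps in cohort.items():
            a, b = setup.score(reps, sensitivity_dtw=f, sensitivity_hmm=f)
            out[f][s] = {"s_d": a.value, "s_h": b.value}
    return out


def quantization_case_table(seed: int) -> dict[str, dict[str, float]]:
    """HMM scores of one participant under three main-feature cluster grids.

    The participant and reference data are identical across cases; only the
    main feature's cluster centers change (3, 4, or 5 evenly spaced
    clusters over [0, 180] degrees; the minor feature keeps 4).  Regrouping
    can put participant and reference frames into different clusters and
    lower the score for one grid but not its neighbors — the quantization
    sensitivity of discrete-HMM scoring.  Demonstration only: which case
    dips depends on where the motion's angles sit relative to the
    boundaries.
    """
    spec = builtin_spec("shoulder_abduction", "left")
    params = default_params(spec, seed=seed)
    ref = simulate_feature_trajectory(params, spec)
    ref_reps = select_scoring_repetitions(segment_repetitions(ref))
    reps = degraded_participant_reps(spec, seed + 100, rom_scale=0.9)

    minor_centers = list(np.linspace(0.0, 180.0, 4))
    cases = {
        "A_3_clusters": list(np.linspace(0.0, 180.0, 3)),
        "B_4_clusters": list(np.linspace(0.0, 180.0, 4)),
        "C_5_clusters": list(np.linspace(0.0, 180.0, 5)),
    }
    out: dict[str, dict[str, float]] = {}
    for name, main_centers in cases.items():
        q = hmm_mod.build_quantizer([main_centers, minor_centers])
        syms_ref = [hmm_mod.quantize(r, q) for r in ref_reps]
        model = hmm_mod.train_reference_hmm(
            syms_ref, seed=seed + 1, n_symbols=q.codebook_size
        )
        mean_len = int(round(np.mean([len(r) for r in ref_reps])))
        bounds = hmm_mod.hmm_lower_bound(spec, q, model, mean_len)
        syms = [hmm_mod.quantize(r, q) for r in reps]
        score = hmm_mod.participant_hmm_score(syms, model, bounds)
        out[name] = {"s_h": score.value, "codebook_size": q.codebook_size}
    return out


def feature_removal_contrast(seed: int, rom_scale: float = 0.7) -> dict[str, float]:
    """Score change from dropping the minor feature, for both methods.

    Removing a minor feature affects the DTW score (every retained feature
    contributes to the Euclidean local cost) more than the HMM score; the
    returned dict carries both full-feature and single-feature scores and
    their absolute changes.
    """
    spec = builtin_spec("hip_abduction", "left")
    minor = 0 if spec.main_feature_index != 0 else 1

    def scores_for(drop: bool):
        setup_spec = spec
        params = default_params(spec, seed=seed)
        ref = simulate_feature_trajectory(params, spec)
        ref_reps = select_scoring_repetitions(segment_repetitions(ref))
        reps = degraded_participant_reps(spec, seed + 100, rom_scale=rom_scale)
        if drop:
            ref_reps = [
                Repetition(r.start_index, r.end_index, drop_feature(r.values, minor))
                for r in ref_reps
            ]
            reps = [
                Repetition(r.start_index, r.end_index, drop_feature(r.values, minor))
                for r in reps
            ]
            setup_spec = reps[0].values.spec
        bounds = dtw_mod.dtw_upper_bound(ref_reps, setup_spec)
        quantizer = hmm_mod.default_quantizer(setup_spec)
        syms_ref = [hmm_mod.quantize(r, quantizer) for r in ref_reps]
        model = hmm_mod.train_reference_hmm(
            syms_ref, seed=seed + 1, n_symbols=quantizer.codebook_size
        )
        mean_len = int(round(np.mean([len(r) for r in ref_reps])))
        hmm_bounds = hmm_mod.hmm_lower_bound(setup_spec, quantizer, model, mean_len)
        s_d = dtw_mod.participant_dtw_score(reps, ref_reps, bounds).value
        syms = [hmm_mod.quantize(r, quantizer) for r in reps]
        s_h = hmm_mod.participant_hmm_score(syms, model, hmm_bounds).value
        return s_d, s_h

    sd_full, sh_full = scores_for(drop=False)
    sd_single, sh_single = scores_for(drop=True)
    return {
        "s_d_full": sd_full,
        "s_d_single": sd_single,
        "s_h_full": sh_full,
        "s_h_single": sh_single,
        "delta_s_d": abs(sd_single - sd_full),
        "delta_s_h": abs(sh_single - sh_full),
    }
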