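"""Discrete-HMM performance scoring.

Feature trajectories are vector-quantized to a finite symbol alphabet
(nearest cluster center per feature, per-feature indices combined row-major
into one product symbol), a single discrete hidden Markov model lambda_R is
trained on the reference repetitions with Baum-Welch, and a performance is
scored by its length-normalized forward log-likelihood

    L = log P(sequence | lambda_R) / length   (always <= 0).

The upper limit is L_u = 0 (a certain sequence); the lower limit L_l is
anchored to the worst performance — the quantized constant rest-pose
trajectory — giving

    S_H = 100 * (L - L_l) / (0 - L_l),  clamped to [0, 100].

Emission probabilities are floored after training so symbols unseen in the
reference (the rest pose typically is) keep a finite log-likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import CategoricalHMM
from scipy.special import logsumexp

from .dtw import worst_trajectory
from .features import ExerciseSpec
from .scores import SimilarityScore, clamp_score

log = logging.getLogger(__name__)

DEFAULT_N_STATES = 5
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-4
EMISSION_FLOOR = 1e-6

#: Spacing of the default coarse quantization grid, degrees.  Quantization
#: for discrete-HMM scoring is deliberately coarse — a handful of clusters
#: per feature — so the few short reference repetitions populate the
#: emission matrix; a finer grid leaves most product symbols unseen and
#: collapses every likelihood toward the floor.
DEFAULT_CENTER_SPACING = 45.0
#: Offset of the transition centers flanking the rest center.  The
#: rest/transition cluster boundary then sits at half this offset (8 deg),
#: inside the segmentation rest band, so the near-rest samples at
#: repetition edges fall into the transition cluster rather than the rest
#: cluster.
_TRANSITION_OFFSET = 16.0
#: Minimum separation kept between quantizer centers.
_MIN_CENTER_SEP = 15.0


@dataclass(frozen=True)
class Quantizer:
    """Per-feature cluster centers; frames map to product symbols."""

    centers: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError("quantizer needs at least one feature")
        for c in self.centers:
            if len(c) < 2:
                raise ValueError("each feature needs >= 2 centers")
            if any(b <= a for a, b in zip(c, c[1:])):
                raise ValueError("centers must be strictly increasing")

    @property
    def n_features(self) -> int:
        return len(self.centers)

    @property
    def codebook_size(self) -> int:
        """M: the product of per-feature center counts."""
        return int(np.prod([len(c) for c in self.centers]))


def build_quantizer(centers_per_feature) -> Quantizer:
    """Build a quantizer from ordered per-feature center lists."""
    return Quantizer(tuple(tuple(float(x) for x in c) for c in centers_per_feature))


def default_quantizer(spec: ExerciseSpec) -> Quantizer:
    """Rest-aware coarse quantizer for a spec's features.

    Each feature gets a narrow dedicated cluster at its rest angle, flanked
    by transition centers, plus a coarse evenly spaced grid over the rest
    of [0, 180] degrees (grid centers too close to an existing center are
    dropped).  The narrow rest cluster is what makes the worst-performance
    bound informative: "not moving" must quantize to a symbol the
    exercising reference essentially never emits — otherwise the constant
    rest sequence, which pays no state-transition costs, becomes *more*
    likely than the reference's own repetitions and L_l collapses toward 0,
    dragging every score with it.
    """
    grid = np.arange(0.0, 180.0 + 1e-9, DEFAULT_CENTER_SPACING)
    centers_per_feature = []
    for rest in spec.rest_pose_angles:
        centers = [float(rest)]
        for t in (rest - _TRANSITION_OFFSET, rest + _TRANSITION_OFFSET):
            if 0.0 <= t <= 180.0:
                centers.append(float(t))
        for g in grid:
            if all(abs(g - c) >= _MIN_CENTER_SEP for c in centers):
                centers.append(float(g))
        centers_per_feature.append(sorted(centers))
    return build_quantizer(centers_per_feature)


def quantize(traj, q: Quantizer, smooth_window: int = 5) -> np.ndarray:
    """Map each frame to its product symbol (nearest center per feature,
    ties broken toward the lower center; row-major index combination).

    Features are smoothed with a centered moving average over
    ``smooth_window`` frames first (pass 1 to disable): sensor jitter on an
    angle sitting near a cluster boundary otherwise makes the symbol flicker
    frame-to-frame, which a discrete HMM punishes severely.
    """
    from scipy.ndimage import uniform_filter1d

    from .dtw import _as_matrix

    x = _as_matrix(traj)
    if smooth_window > 1 and x.shape[0] > 1:
        x = uniform_filter1d(x, size=smooth_window, axis=0, mode="nearest")
    if x.shape[1] != q.n_features:
        raise ValueError(
            f"feature-count mismatch: trajectory has {x.shape[1]}, "
            f"quantizer has {q.n_features}"
        )
    sizes = [len(c) for c in q.centers]
    strides = np.ones(len(sizes), dtype=int)
    for f in range(len(sizes) - 2, -1, -1):
        strides[f] = strides[f + 1] * sizes[f + 1]
    symbols = np.zeros(x.shape[0], dtype=int)
    for f, centers in enumerate(q.centers):
        c = np.asarray(centers)
        # argmin returns the first (lower) center on ties
        idx = np.argmin(np.abs(x[:, [f]] - c[None, :]), axis=1)
        symbols += idx * strides[f]
    return symbols


@dataclass
class DiscreteHMM:
    """A discrete-observation HMM: transition A (NxN), emission B (NxM),
    initial state distribution; rows are stochastic."""

    transition: np.ndarray
    emission: np.ndarray
    initial: np.ndarray
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        n = self.transition.shape[0]
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if self.emission.shape[0] != n or self.initial.shape != (n,):
            raise ValueError("inconsistent state counts")
        for name, mat in (("transition", self.transition), ("emission", self.emission)):
            if mat.min() < 0 or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must be stochastic")
        if self.initial.min() < 0 or not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must be stochastic")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[1]


@dataclass
class LikelihoodResult:
    """Length-normalized forward log-likelihood of one symbol sequence."""

    loglik_per_frame: float
    sequence_length: int

    def __post_init__(self) -> None:
        if self.loglik_per_frame > 1e-12:
            raise ValueError("per-frame log-likelihood must be <= 0")


@dataclass
class HmmScoreBounds:
    """Worst-performance normalizer for HMM scores: L in [L_l, 0]."""

    l_lower: float
    l_upper: float = 0.0
    sensitivity_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.l_lower >= 0:
            raise ValueError("degenerate bound: L_l must be < 0")
        if self.sensitivity_factor <= 0:
            raise ValueError("sensitivity_factor must be > 0")

    @property
    def effective_lower(self) -> float:
        return self.l_lower * self.sensitivity_factor

    def scaled(self, factor: float) -> "HmmScoreBounds":
        return HmmScoreBounds(self.l_lower, self.l_upper, self.sensitivity_factor * factor)


class _HistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that records every per-iteration log-likelihood."""

    def __init__(self, tol, n_iter):
        super().__init__(tol, n_iter, verbose=False)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _floor_rows(mat: np.ndarray, floor: float) -> np.ndarray:
    out = np.maximum(mat, floor)
    return out / out.sum(axis=1, keepdims=True)


def train_reference_hmm(
    reference_symbol_seqs,
    n_states: int = DEFAULT_N_STATES,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_symbols: int | None = None,
    emission_floor: float = EMISSION_FLOOR,
    n_restarts: int = 3,
) -> DiscreteHMM:
    """Baum-Welch estimation of the reference model from symbol sequences.

    Initialization: uniform initial distribution; A and B start from a
    seeded uniform-random perturbation of uniform rows (ergodic topology).
    EM is restarted ``n_restarts`` times from distinct seeded
    perturbations and the fit with the highest final training
    log-likelihood is kept, the usual guard against local optima.  The
    per-iteration total log-likelihood of the kept run is non-decreasing
    (EM guarantee) and is retained in ``training_history``.  After
    fitting, emission rows are floored at ``emission_floor`` and
    renormalized.
    """
    seqs = [np.asarray(s, dtype=int).ravel() for s in reference_symbol_seqs]
    if not seqs or any(len(s) == 0 for s in seqs):
        raise ValueError("empty training set")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    max_sym = max(int(s.max()) for s in seqs)
    m = n_symbols if n_symbols is not None else max_sym + 1
    if max_sym >= m:
        raise ValueError("symbol out of range for n_symbols")

    X = np.concatenate(seqs)[:, None]
    lengths = [len(s) for s in seqs]
    # reference models are deliberately over-parameterized relative to the
    # few short training repetitions; silence hmmlearn's warning about it
    hmm_log = logging.getLogger("hmmlearn.base")
    old_level = hmm_log.level
    hmm_log.setLevel(logging.ERROR)
    best = None
    try:
        for r in range(n_restarts):
            rng = np.random.default_rng(seed + 7919 * r)
            model = CategoricalHMM(
                n_components=n_states,
                n_iter=max_iter,
                tol=tol,
                init_params="",
                params="ste",
                random_state=seed + r,
            )
            model.n_features = m
            model.startprob_ = np.full(n_states, 1.0 / n_states)
            model.transmat_ = _floor_rows(1.0 + 0.1 * rng.random((n_states, n_states)), 0.0)
            model.emissionprob_ = _floor_rows(1.0 + 0.1 * rng.random((n_states, m)), 0.0)
            model.monitor_ = _HistoryMonitor(model.tol, model.n_iter)
            model.fit(X, lengths)
            final = model.monitor_.full_history[-1]
            if best is None or final > best.monitor_.full_history[-1]:
                best = model
    finally:
        hmm_log.setLevel(old_level)

    return DiscreteHMM(
        transition=_floor_rows(np.maximum(best.transmat_, 0.0), 0.0),
        emission=_floor_rows(best.emissionprob_, emission_floor),
        initial=np.maximum(best.startprob_, 0.0) / best.startprob_.sum(),
        training_history=list(best.monitor_.full_history),
    )


def log_likelihood(seq, model: DiscreteHMM) -> LikelihoodResult:
    """Forward algorithm in log space; returns log P(seq | model) / len(seq)."""
    s = np.asarray(seq, dtype=int).ravel()
    if len(s) == 0:
        raise ValueError("empty sequence")
    if s.min() < 0 or s.max() >= model.n_symbols:
        raise ValueError("symbol out of range")
    with np.errstate(divide="ignore"):
        log_a = np.log(model.transition)
        log_b = np.log(model.emission)
        log_pi = np.log(model.initial)
    alpha = log_pi + log_b[:, s[0]]
    for sym in s[1:]:
        alpha = logsumexp(alpha[:, None] + log_a, axis=0) + log_b[:, sym]
    total = float(logsumexp(alpha))
    return LikelihoodResult(min(total / len(s), 0.0), len(s))


def hmm_lower_bound(
    spec: ExerciseSpec,
    q: Quantizer,
    model: DiscreteHMM,
    length: int,
    sensitivity_factor: float = 1.0,
) -> HmmScoreBounds:
    """L_l from the worst performance: the quantized constant rest trajectory."""
    worst = quantize(worst_trajectory(spec, length), q)
    l_l = log_likelihood(worst, model).loglik_per_frame
    if l_l >= 0:
        raise ValueError(
            "degenerate bound: worst performance is indistinguishable from "
            "the reference model"
        )
    return HmmScoreBounds(l_l, 0.0, sensitivity_factor)


def hmm_similarity(L: float, bounds: HmmScoreBounds) -> SimilarityScore:
    """Convert one per-frame log-likelihood into a percentage score."""
    l_l = bounds.effective_lower
    raw = 100.0 * (L - l_l) / (0.0 - l_l)
    if raw < 0:
        log.info("log-likelihood %.4f below effective bound %.4f; clamped to 0", L, l_l)
    return SimilarityScore(clamp_score(raw), "hmm", [raw])


def participant_hmm_score(
    participant_reps, model: DiscreteHMM, bounds: HmmScoreBounds
) -> SimilarityScore:
    """Per-repetition likelihood scores (3 under the standard protocol), averaged."""
    reps = list(participant_reps)
    if not reps:
        raise ValueError("empty repetition list")
    l_l = bounds.effective_lower
    per_rep = []
    for rep in reps:
        L = log_likelihood(rep, model).loglik_per_frame
        per_rep.append(100.0 * (L - l_l) / (0.0 - l_l))
    return SimilarityScore(clamp_score(float(np.mean(per_rep))), "hmm", per_rep)


# ---------------------------------------------------------------------------
# Model serialization (round-trippable JSON)

def save_model(model: DiscreteHMM, q: Quantizer, path: str | Path) -> None:
    payload = {
        "n_states": model.n_states,
        "n_symbols": model.n_symbols,
        "transition": model.transition.tolist(),
        "emission": model.emission.tolist(),
        "initial": model.initial.tolist(),
        "quantizer_centers": [list(c) for c in q.centers],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[DiscreteHMM, Quantizer]:
    payload = json.loads(Path(path).read_text())
    model = DiscreteHMM(
        np.array(payload["transition"]),
        np.array(payload["emission"]),
        np.array(payload["initial"]),
    )
    return model, build_quantizer(payload["quantizer_centers"])
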