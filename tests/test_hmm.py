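import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exerscore import (
    DiscreteHMM,
    HmmScoreBounds,
    build_quantizer,
    builtin_spec,
    default_quantizer,
    hmm_lower_bound,
    hmm_similarity,
    log_likelihood,
    participant_hmm_score,
    quantize,
    train_reference_hmm,
    worst_trajectory,
)
from exerscore.hmm import load_model, save_model
from tests.conftest import brute_force_forward


def _random_model(rng, n_states, n_symbols):
    def stochastic(shape):
        m = rng.random(shape) + 0.05
        return m / m.sum(axis=-1, keepdims=True)

    return DiscreteHMM(
        stochastic((n_states, n_states)),
        stochastic((n_states, n_symbols)),
        stochastic(n_states),
    )


class TestQuantizer:
    def test_codebook_size_is_product(self):
        q = build_quantizer([(90, 180, 270), (90, 150, 210, 270)])
        assert q.codebook_size == 12

    def test_two_centers_single_feature(self):
        assert build_quantizer([(0, 90)]).codebook_size == 2

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            build_quantizer([(90, 90)])

    def test_nearest_center_assignment(self):
        q = build_quantizer([(90, 180, 270)])
        assert quantize(np.array([[100.0]]), q)[0] == 0

    def test_tie_breaks_toward_lower_center(self):
        q = build_quantizer([(90, 180, 270)])
        assert quantize(np.array([[135.0]]), q)[0] == 0

    def test_row_major_product_symbol(self):
        q = build_quantizer([(90, 180, 270), (90, 150, 210, 270)])
        # theta1=100 -> index 0 (stride 4); theta2=160 -> index 1
        assert quantize(np.array([[100.0, 160.0]]), q)[0] == 1

    def test_column_mismatch_rejected(self):
        q = build_quantizer([(90, 180)])
        with pytest.raises(ValueError, match="mismatch"):
            quantize(np.zeros((3, 2)), q)

    def test_smoothing_removes_boundary_flicker(self):
        # signal sits just above the 5.0 cluster boundary; frame-to-frame
        # jitter crosses it, the smoothed average does not
        q = build_quantizer([(0, 10)])
        x = (5.3 + np.array([0.6, -0.6] * 10))[:, None]
        flickery = quantize(x, q, smooth_window=1)
        smoothed = quantize(x, q)
        interior = slice(2, -2)  # window edges see asymmetric padding
        assert len(set(flickery[interior].tolist())) == 2
        assert len(set(smoothed[interior].tolist())) == 1

    def test_default_quantizer_isolates_rest_pose(self):
        spec = builtin_spec("shoulder_abduction", "left")
        q = default_quantizer(spec)
        rest_sym = quantize(worst_trajectory(spec, 1), q)[0]
        # 16 degrees away from rest already falls into another cluster
        moved = np.array([[spec.rest_pose_angles[0] + 16.0, spec.rest_pose_angles[1]]])
        assert quantize(moved, q)[0] != rest_sym


class TestForwardAlgorithm:
    def test_certain_sequence_has_zero_loglik(self):
        model = DiscreteHMM(np.eye(1), np.array([[1.0, 0.0]]), np.array([1.0]))
        assert log_likelihood([0, 0, 0], model).loglik_per_frame == 0.0

    def test_improbable_symbol_gives_negative_loglik(self):
        model = DiscreteHMM(
            np.eye(1), np.array([[1.0 - 1e-6, 1e-6]]), np.array([1.0])
        )
        assert log_likelihood([0, 1, 0], model).loglik_per_frame < 0.0

    def test_symbol_out_of_range_rejected(self):
        model = DiscreteHMM(np.eye(1), np.array([[0.5, 0.5]]), np.array([1.0]))
        with pytest.raises(ValueError, match="out of range"):
            log_likelihood([2], model)

    @settings(deadline=None, max_examples=100)
    @given(
        n_states=st.integers(1, 3),
        n_symbols=st.integers(2, 4),
        length=st.integers(1, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_path_sum(self, n_states, n_symbols, length, seed):
        """Forward log-likelihood equals the exhaustive sum over all N^l
        hidden state paths."""
        rng = np.random.default_rng(seed)
        model = _random_model(rng, n_states, n_symbols)
        seq = rng.integers(0, n_symbols, size=length)
        expected = brute_force_forward(seq, model) / length
        got = log_likelihood(seq, model).loglik_per_frame
        assert got == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_hmmlearn(self):
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(7)
        model = _random_model(rng, 4, 5)
        seq = rng.integers(0, 5, size=40)
        ref = CategoricalHMM(n_components=4)
        ref.n_features = 5
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.emissionprob_ = model.emission
        expected = ref.score(seq[:, None]) / len(seq)
        assert log_likelihood(seq, model).loglik_per_frame == pytest.approx(expected, abs=1e-9)


class TestBaumWelch:
    def test_degenerate_single_state_fit(self):
        model = train_reference_hmm([[0, 0, 0, 0]], n_states=1, seed=0, n_symbols=2)
        assert model.emission[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert log_likelihood([0, 0, 0], model).loglik_per_frame == pytest.approx(0.0, abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_training_loglik_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [rng.integers(0, 6, size=rng.integers(20, 40)) for _ in range(3)]
        model = train_reference_hmm(seqs, n_states=3, seed=seed, n_symbols=6)
        history = np.asarray(model.training_history)
        assert len(history) >= 2
        assert np.all(np.diff(history) >= -1e-8)

    def test_stochastic_matrix_invariants(self):
        rng = np.random.default_rng(1)
        seqs = [rng.integers(0, 4, size=30) for _ in range(3)]
        model = train_reference_hmm(seqs, n_states=4, seed=2, n_symbols=4)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.emission.sum(axis=1), 1.0, atol=1e-9)
        assert model.initial.sum() == pytest.approx(1.0, abs=1e-9)
        assert model.emission.min() > 0  # floored

    def test_two_state_parameter_recovery(self):
        """Baum-Welch recovers a well-separated 2-state generator to 0.1
        (up to state permutation) from 50 sequences."""
        true_a = np.array([[0.9, 0.1], [0.1, 0.9]])
        true_b = np.array([[0.9, 0.1], [0.1, 0.9]])
        rng = np.random.default_rng(12345)
        seqs = []
        for _ in range(50):
            state = 0
            seq = []
            for _ in range(60):
                seq.append(rng.choice(2, p=true_b[state]))
                state = rng.choice(2, p=true_a[state])
            seqs.append(seq)
        model = train_reference_hmm(seqs, n_states=2, seed=9, n_symbols=2)
        errs = []
        for perm in itertools.permutations(range(2)):
            p = list(perm)
            errs.append(
                max(
                    np.abs(model.transition[p][:, p] - true_a).max(),
                    np.abs(model.emission[p] - true_b).max(),
                )
            )
        assert min(errs) < 0.1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            train_reference_hmm([], n_states=2)
        with pytest.raises(ValueError):
            train_reference_hmm([[0, 1]], n_states=0)


@pytest.fixture(scope="module")
def setup():
    from exerscore.experiments import build_reference_setup

    spec = builtin_spec("shoulder_abduction", "left")
    return build_reference_setup(spec, seed=21)


class TestBoundsAndScores:
    def test_lower_bound_negative_for_moving_reference(self, setup):
        assert setup.hmm_bounds.l_lower < 0

    def test_degenerate_bound_for_rest_trained_model(self):
        spec = builtin_spec("shoulder_abduction", "left")
        q = default_quantizer(spec)
        rest_syms = quantize(worst_trajectory(spec, 60), q)
        model = train_reference_hmm([rest_syms], n_states=1, seed=0,
                                    n_symbols=q.codebook_size, emission_floor=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            hmm_lower_bound(spec, q, model, 30)

    @pytest.mark.parametrize(
        "L, expected", [(0.0, 100.0), (-2.0, 0.0), (-1.0, 50.0)]
    )
    def test_similarity_linear_in_loglik(self, L, expected):
        bounds = HmmScoreBounds(-2.0)
        assert hmm_similarity(L, bounds).value == pytest.approx(expected)

    def test_sensitivity_factor_scales_effective_bound(self):
        bounds = HmmScoreBounds(-2.0)
        assert bounds.scaled(0.5).effective_lower == pytest.approx(-1.0)
        assert hmm_similarity(-0.5, bounds.scaled(2.0)).value > hmm_similarity(
            -0.5, bounds
        ).value

    def test_three_per_repetition_values(self, setup):
        syms = [quantize(r, setup.quantizer) for r in setup.reference_reps]
        score = participant_hmm_score(syms, setup.model, setup.hmm_bounds)
        assert len(score.per_pair_values) == 3

    def test_reference_outscores_degraded_participant(self, setup):
        from exerscore.experiments import degraded_participant_reps

        spec = setup.spec
        syms_ref = [quantize(r, setup.quantizer) for r in setup.reference_reps]
        self_score = participant_hmm_score(syms_ref, setup.model, setup.hmm_bounds)
        reps = degraded_participant_reps(spec, seed=500, rom_scale=0.5)
        syms_deg = [quantize(r, setup.quantizer) for r in reps]
        degraded = participant_hmm_score(syms_deg, setup.model, setup.hmm_bounds)
        assert self_score.value > degraded.value

    def test_rest_participant_scores_near_zero(self, setup):
        syms = [quantize(worst_trajectory(setup.spec, 40), setup.quantizer)] * 3
        score = participant_hmm_score(syms, setup.model, setup.hmm_bounds)
        assert score.value <= 5.0

    def test_duration_robustness(self):
        """Uniform time-stretching (frame duplication) changes the per-frame
        log-likelihood by less than 10% relative when self-transitions
        dominate the per-frame cost — performing slower barely moves L."""
        model = DiscreteHMM(
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            np.array([[0.95, 0.05], [0.05, 0.95]]),
            np.array([0.5, 0.5]),
        )
        syms = np.array([0] * 60 + [1] * 60)
        stretched = np.repeat(syms, 2)
        L0 = log_likelihood(syms, model).loglik_per_frame
        L1 = log_likelihood(stretched, model).loglik_per_frame
        assert abs(L1 - L0) / abs(L0) < 0.10


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    model = _random_model(rng, 3, 5)
    q = build_quantizer([(10, 50, 90), (20, 80)])
    save_model(model, q, tmp_path / "m.json")
    back_model, back_q = load_model(tmp_path / "m.json")
    np.testing.assert_allclose(back_model.transition, model.transition, atol=1e-12)
    np.testing.assert_allclose(back_model.emission, model.emission, atol=1e-12)
    np.testing.assert_allclose(back_model.initial, model.initial, atol=1e-12)
    assert back_q == q
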