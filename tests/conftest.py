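import numpy as np
import pytest

from exerscore import (
    builtin_spec,
    default_params,
    simulate_feature_trajectory,
    simulate_skeleton_session,
)


@pytest.fixture(scope="session")
def shoulder_spec():
    return builtin_spec("shoulder_abduction", "left")


@pytest.fixture(scope="session")
def hip_spec():
    return builtin_spec("hip_abduction", "left")


@pytest.fixture(scope="session")
def shoulder_trajectory(shoulder_spec):
    """A default 5-repetition noisy shoulder-abduction trajectory."""
    return simulate_feature_trajectory(default_params(shoulder_spec, seed=11), shoulder_spec)


@pytest.fixture(scope="session")
def small_session(shoulder_spec):
    """A short noise-free skeleton session (2 repetitions, cheap to build)."""
    params = default_params(
        shoulder_spec, seed=0, noise_sd=0.0, n_reps=2, rep_duration=1.0, pause_duration=0.5
    )
    return simulate_skeleton_session(params, shoulder_spec)


def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive minimum alignment cost over all monotone warping paths."""
    a = np.atleast_2d(a.T).T if a.ndim == 1 else a
    b = np.atleast_2d(b.T).T if b.ndim == 1 else b
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        cost = float(np.linalg.norm(a[i] - b[j]))
        if i == 0 and j == 0:
            return cost
        options = []
        if i > 0:
            options.append(best(i - 1, j))
        if j > 0:
            options.append(best(i, j - 1))
        if i > 0 and j > 0:
            options.append(best(i - 1, j - 1))
        return cost + min(options)

    return best(len(a) - 1, len(b) - 1)


def brute_force_forward(seq, model) -> float:
    """log P(seq | model) by explicit summation over all state paths."""
    import itertools

    n = model.n_states
    total = 0.0
    for path in itertools.product(range(n), repeat=len(seq)):
        p = model.initial[path[0]] * model.emission[path[0], seq[0]]
        for t in range(1, len(seq)):
            p *= model.transition[path[t - 1], path[t]] * model.emission[path[t], seq[t]]
        total += p
    return float(np.log(total))
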