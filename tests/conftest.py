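import numpy as np
import pytest

from mmbreast import PhantomSpec, builtin_profiles
from mmbreast.phantom import MuellerFieldTruth


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture
def small_spec():
    """A cheap 16x16 phantom spec for unit tests."""
    return PhantomSpec(
        cohort_counts={"healthy": 2, "benign": 1, "grade2": 1, "grade3": 1},
        images_per_sample=2,
        height=16,
        width=16,
        seed=42,
    )


def constant_field(matrix: np.ndarray, shape=(8, 8), sample_id="S0", label="healthy"):
    """Truth field whose every pixel carries the same 4x4 Mueller matrix."""
    el = np.asarray(matrix, float).reshape(16, 1, 1) * np.ones((16,) + shape)
    return MuellerFieldTruth(sample_id=sample_id, label=label, elements=el)


def run_with_retry(check, seeds):
    """Two-stage stochastic check with pre-registered seeds.

    Runs ``check(seeds[0])``; if that fails its (typically ~2-sigma)
    assertion, runs ``check(seeds[1])`` once.  A genuine systematic bias
    fails both draws; a Monte-Carlo fluke (~5% per draw) almost never does
    (~0.25% joint).
    """
    try:
        return check(seeds[0])
    except AssertionError:
        return check(seeds[1])


def random_passive_matrix(rng: np.random.Generator) -> np.ndarray:
    """Random Mueller matrix with m11 = 1 whose 36 canonical-state
    intensities are strictly positive (off-elements bounded by 0.3, so any
    signed triple sums to less than 1)."""
    M = rng.uniform(-0.3, 0.3, (4, 4))
    M[0, 0] = 1.0
    return M
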