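import numpy as np
import pytest

from mmbreast import canonical_states, element_mueller, simulate_stack
from mmbreast.polarimeter import NOISELESS, NoiseConfig, PolarizationStack, STATE_LABELS

from conftest import constant_field


def test_canonical_states_definitions():
    states = {s.label: np.array(s.stokes) for s in canonical_states()}
    np.testing.assert_array_equal(states["H"], [1, 1, 0, 0])
    np.testing.assert_array_equal(states["V"], [1, -1, 0, 0])
    np.testing.assert_array_equal(states["P"], [1, 0, 1, 0])
    np.testing.assert_array_equal(states["M"], [1, 0, -1, 0])
    np.testing.assert_array_equal(states["R"], [1, 0, 0, 1])
    np.testing.assert_array_equal(states["L"], [1, 0, 0, -1])
    for s in states.values():
        assert s[0] == 1
        assert s[1] ** 2 + s[2] ** 2 + s[3] ** 2 == pytest.approx(1)
    # antipodal pairs are orthogonal in the polarized part
    for a, b in [("H", "V"), ("P", "M"), ("R", "L")]:
        assert np.dot(states[a][1:], states[b][1:]) == pytest.approx(-1)


def test_polarizer_produces_linear_states():
    unpolarized = np.array([1.0, 0, 0, 0])
    out = element_mueller("linear_polarizer", 0.0) @ unpolarized
    np.testing.assert_allclose(out / out[0], [1, 1, 0, 0], atol=1e-12)
    out45 = element_mueller("linear_polarizer", 45.0) @ unpolarized
    np.testing.assert_allclose(out45 / out45[0], [1, 0, 1, 0], atol=1e-12)


def test_quarter_wave_plate_makes_circular_from_h():
    h = np.array([1.0, 1.0, 0, 0])
    out = element_mueller("quarter_wave_plate", 45.0) @ h
    assert abs(out[3]) == pytest.approx(1.0, abs=1e-12)
    assert out[1] == pytest.approx(0, abs=1e-12)


@pytest.mark.parametrize("angle", np.linspace(0, 180, 13))
def test_polarizer_idempotent_up_to_scale(angle):
    # M = (1/2) u u^T with u = (1, cos2t, sin2t, 0) and u^T u = 2, so the
    # ideal polarizer is exactly idempotent (proportionality constant 1)
    P = element_mueller("linear_polarizer", angle)
    np.testing.assert_allclose(P @ P, P, atol=1e-12)


def test_psg_psa_trains_realize_canonical_states():
    """Polarizer (+ quarter-wave plate for circular states) reproduces the
    six probe states from unpolarized source light."""
    unpolarized = np.array([1.0, 0, 0, 0])
    by_label = {s.label: np.array(s.stokes) for s in canonical_states()}
    for label, angle in [("H", 0.0), ("P", 45.0), ("V", 90.0), ("M", 135.0)]:
        out = element_mueller("linear_polarizer", angle) @ unpolarized
        np.testing.assert_allclose(out / out[0], by_label[label], atol=1e-12)
    for label, qwp_angle in [("R", 45.0), ("L", -45.0)]:
        train = element_mueller("quarter_wave_plate", qwp_angle) @ element_mueller(
            "linear_polarizer", 0.0
        )
        out = train @ unpolarized
        np.testing.assert_allclose(out / out[0], by_label[label], atol=1e-12)


def test_unknown_element_kind_rejected():
    with pytest.raises(ValueError):
        element_mueller("half_wave_plate", 0.0)


def test_identity_sample_intensities():
    truth = constant_field(np.eye(4))
    stack = simulate_stack(truth, NOISELESS, gain=2.0)
    np.testing.assert_allclose(stack.images[("H", "H")], 2.0)
    np.testing.assert_allclose(stack.images[("H", "V")], 0.0, atol=1e-15)


def test_perfect_depolarizer_flat_stack():
    truth = constant_field(np.diag([1.0, 0, 0, 0]))
    stack = simulate_stack(truth, NOISELESS, gain=3.0)
    for img in stack.images.values():
        np.testing.assert_allclose(img, 1.5)


def test_stack_linearity_in_truth():
    rng = np.random.default_rng(0)
    A = rng.uniform(-0.2, 0.2, (4, 4))
    A[0, 0] = 1.0
    B = rng.uniform(-0.2, 0.2, (4, 4))
    B[0, 0] = 1.0
    sa = simulate_stack(constant_field(A), NOISELESS)
    sb = simulate_stack(constant_field(B), NOISELESS)
    sab = simulate_stack(constant_field((A + B)), NOISELESS)
    for pair in sab.images:
        np.testing.assert_allclose(
            sab.images[pair], sa.images[pair] + sb.images[pair], atol=1e-12
        )


def test_unphysical_truth_rejected():
    M = np.eye(4)
    M[0, 0] = 1.0
    M[1, 1] = -1.5  # drives I_HH below zero
    truth = constant_field(M)
    with pytest.raises(ValueError, match="negative noiseless intensity"):
        simulate_stack(truth, NOISELESS)


def test_noise_reproducible_and_floored():
    truth = constant_field(np.diag([1.0, 0.1, 0.1, 0.1]), shape=(16, 16))
    noise = NoiseConfig(shot_noise=True, read_noise_sd=0.02, seed=9)
    s1 = simulate_stack(truth, noise)
    s2 = simulate_stack(truth, noise)
    for pair in s1.images:
        np.testing.assert_array_equal(s1.images[pair], s2.images[pair])
        assert (s1.images[pair] >= 0).all()
    s3 = simulate_stack(truth, NoiseConfig(shot_noise=True, read_noise_sd=0.02, seed=10))
    assert any(
        not np.array_equal(s1.images[p], s3.images[p]) for p in s1.images
    )


def test_incomplete_stack_rejected():
    truth = constant_field(np.eye(4))
    stack = simulate_stack(truth, NOISELESS)
    images = dict(stack.images)
    images.pop(("P", "M"))
    with pytest.raises(ValueError, match="missing state pairs"):
        PolarizationStack(sample_id="S0", images=images)


def test_stack_has_36_state_pairs():
    truth = constant_field(np.eye(4))
    stack = simulate_stack(truth, NOISELESS)
    assert len(stack.images) == 36
    assert {x for x, _ in stack.images} == set(STATE_LABELS)
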