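"""Activation functions, sharpening convolution, attention gate, loss family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoseg import (
    LossConfig,
    SHARPEN_KERNEL,
    attention_gate,
    bce_dice_loss,
    bce_loss,
    dice_coefficient,
    dice_loss,
    leaky_relu,
    mish,
    sharpen_features,
    swish,
)
from sonoseg.components import activation, relu, sigmoid


# ---------------------------------------------------------------- activations

@pytest.mark.parametrize(
    "fn, x, expected",
    [
        (swish, 0.0, 0.0),
        (swish, 1.0, 0.731059),
        (mish, 0.0, 0.0),
        (mish, 1.0, 0.865098),
        (lambda x: leaky_relu(x, 0.1), 2.0, 2.0),
        (lambda x: leaky_relu(x, 0.1), -2.0, -0.2),
    ],
)
def test_activation_point_values(fn, x, expected):
    assert fn(x) == pytest.approx(expected, abs=1e-5)


def test_swish_asymptotically_linear():
    assert swish(20.0) == pytest.approx(20.0, abs=1e-6)


def test_mish_retains_small_negative_tail():
    v = mish(-20.0)
    assert -1e-6 < v < 0.0
    assert v == pytest.approx(-4.1e-8, rel=0.05)


def test_leaky_relu_alpha_zero_is_relu(rng):
    x = rng.standard_normal(100)
    np.testing.assert_array_equal(leaky_relu(x, 0.0), relu(x))


def test_leaky_relu_rejects_negative_slope():
    with pytest.raises(ValueError):
        leaky_relu(1.0, alpha=-0.1)


@pytest.mark.parametrize("fn", [swish, mish])
def test_smooth_activations_dip_negative_then_track_identity(fn):
    xs = np.linspace(-5, 5, 201)
    ys = fn(xs)
    assert ys.min() < 0.0  # small negative dip
    assert np.any(np.diff(ys) < 0)  # non-monotonic
    assert fn(50.0) / 50.0 == pytest.approx(1.0, abs=1e-9)


def test_unknown_activation_name_raises():
    with pytest.raises(ValueError, match="unknown activation"):
        activation("gelu", 1.0)


# ---------------------------------------------------------------- sharpening

def test_sharpen_kernel_has_unit_dc_gain_and_symmetry():
    assert SHARPEN_KERNEL.sum() == 1.0
    np.testing.assert_array_equal(SHARPEN_KERNEL, SHARPEN_KERNEL[::-1, ::-1])


def test_sharpen_constant_map_unchanged_in_interior():
    out = sharpen_features(np.full((9, 9), 3.7))
    np.testing.assert_allclose(out[1:-1, 1:-1], 3.7, atol=1e-12)


def test_sharpen_impulse_reproduces_kernel():
    imp = np.zeros((7, 7))
    imp[3, 3] = 1.0
    out = sharpen_features(imp)
    np.testing.assert_allclose(out[2:5, 2:5], SHARPEN_KERNEL, atol=1e-12)


def _brute_force_depthwise(fm, kernel):
    """Nested-loop 'same' convolution oracle, zero padding."""
    h, w, c = fm.shape
    kf = kernel[::-1, ::-1]
    out = np.zeros_like(fm)
    for ch in range(c):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for di in range(3):
                    for dj in range(3):
                        ii, jj = i + di - 1, j + dj - 1
                        if 0 <= ii < h and 0 <= jj < w:
                            acc += kf[di, dj] * fm[ii, jj, ch]
                out[i, j, ch] = acc
    return out


def test_sharpen_matches_brute_force_oracle(rng):
    fm = rng.standard_normal((8, 8, 2))
    np.testing.assert_allclose(
        sharpen_features(fm), _brute_force_depthwise(fm, np.asarray(SHARPEN_KERNEL)),
        atol=1e-6,
    )


def test_sharpen_rejects_tiny_spatial_dims():
    with pytest.raises(ValueError):
        sharpen_features(np.ones((2, 2, 1)))


# ------------------------------------------------------------- attention gate

def test_attention_gate_zero_collapse_weights_halve_input(rng):
    x = rng.standard_normal((5, 5, 3))
    g = rng.standard_normal((5, 5, 3))
    wx = rng.standard_normal((3, 2))
    wg = rng.standard_normal((3, 2))
    out, coeff = attention_gate(x, g, wx, wg, np.zeros((2, 1)))
    np.testing.assert_allclose(coeff, 0.5)
    np.testing.assert_allclose(out, 0.5 * x)


def test_attention_gate_scalar_hand_computation():
    out, coeff = attention_gate(
        np.array([[[2.0]]]), np.array([[[3.0]]]), [[1.0]], [[1.0]], [[1.0]]
    )
    assert coeff.ravel()[0] == pytest.approx(sigmoid(swish(5.0)), abs=1e-9)
    assert out.ravel()[0] == pytest.approx(1.98612, abs=1e-4)


def test_attention_gate_attenuates_never_amplifies(rng):
    x = rng.standard_normal((6, 6, 4))
    g = rng.standard_normal((6, 6, 2))
    out, coeff = attention_gate(
        x, g, rng.standard_normal((4, 3)), rng.standard_normal((2, 3)),
        rng.standard_normal((3, 1)),
    )
    assert np.all(np.abs(out) <= np.abs(x))
    assert np.all((coeff > 0) & (coeff < 1))


def test_attention_gate_spatial_mismatch_raises(rng):
    with pytest.raises(ValueError, match="spatial mismatch"):
        attention_gate(
            np.zeros((4, 4, 1)), np.zeros((5, 5, 1)), [[1.0]], [[1.0]], [[1.0]]
        )


# ---------------------------------------------------------------- loss family

def test_bce_worked_examples():
    assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2), abs=1e-9)
    assert bce_loss([1.0, 0.0], [0.9, 0.1]) == pytest.approx(0.105361, abs=1e-6)


def test_bce_perfect_binary_prediction_is_tiny():
    cfg = LossConfig()
    y = np.array([1.0, 0.0, 1.0])
    bound = 2 * cfg.epsilon_log * abs(np.log(cfg.epsilon_log))
    assert bce_loss(y, y, cfg) <= bound


def test_soft_dice_counting_oracle():
    y = np.array([1, 1, 1, 1, 0, 0], dtype=float)
    p = np.array([1, 1, 0, 0, 0, 0], dtype=float)
    assert dice_coefficient(y, p) == pytest.approx(2 / 3, abs=1e-4)
    assert dice_loss(y, p) == pytest.approx(1 / 3, abs=1e-4)


def test_dice_degenerate_cases():
    y4 = np.array([1.0] * 4 + [0.0] * 4)
    zeros = np.zeros(8)
    assert dice_coefficient(y4, y4) == pytest.approx(1.0, abs=1e-5)
    assert dice_coefficient(y4, zeros) == pytest.approx(0.0, abs=1e-5)
    # all-background 0/0 convention: perfect agreement scores 1
    assert dice_coefficient(zeros, zeros) == pytest.approx(1.0)


def test_dice_symmetric_in_arguments(rng):
    y = rng.random(50)
    p = rng.random(50)
    assert dice_coefficient(y, p) == pytest.approx(dice_coefficient(p, y), abs=1e-12)


def test_bce_dice_single_pixel_hand_value():
    assert bce_dice_loss([1.0], [0.5]) == pytest.approx(1.026480, abs=1e-4)


def test_bce_dice_dominates_both_components(rng):
    y = (rng.random((4, 4)) > 0.5).astype(float)
    p = rng.random((4, 4))
    total = bce_dice_loss(y, p)
    assert total >= bce_loss(y, p) - 1e-12
    assert total >= dice_loss(y, p) - 1e-12


@settings(deadline=None, max_examples=30)
@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
def test_bce_dice_decreases_as_prediction_approaches_target(p_far, p_near):
    y = np.array([1.0])
    lo, hi = sorted((p_far, p_near))
    assert bce_dice_loss(y, np.array([hi])) <= bce_dice_loss(y, np.array([lo])) + 1e-12


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape mismatch"):
        bce_loss(np.zeros(3), np.zeros(4))


def test_loss_config_validates_epsilons():
    with pytest.raises(ValueError):
        LossConfig(epsilon_dice=0.5)
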