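"""Numerical building blocks of the segmentation networks.

Everything here is plain-numpy and stateless: smooth activation functions
(with their derivatives, used by the autodiff core), the fixed Laplacian-style
sharpening convolution applied on skip connections, the additive attention
gate in functional form, and the BCE + soft-Dice compound loss family used to
train the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "SHARPEN_KERNEL",
    "sigmoid",
    "relu",
    "leaky_relu",
    "swish",
    "mish",
    "activation",
    "activation_grad",
    "sharpen_features",
    "attention_gate",
    "bce_loss",
    "dice_coefficient",
    "dice_loss",
    "bce_dice_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Numerical guards for the compound loss.

    epsilon_dice stabilises the soft-Dice ratio (and makes the all-background
    0/0 case evaluate to 1); epsilon_log clips predicted probabilities away
    from {0, 1} before the cross-entropy logarithms.
    """

    epsilon_dice: float = 1e-5
    epsilon_log: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("epsilon_dice", "epsilon_log"):
            v = getattr(self, name)
            if not (0.0 < v < 1e-2):
                raise ValueError(f"{name} must lie in (0, 1e-2), got {v}")


#: Fixed 3x3 sharpening mask used on the skip connections. Unit DC gain
#: (entries sum to 1) so constant regions pass through unchanged, while
#: intensity transitions are amplified. Never trainable.
SHARPEN_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]]
)
SHARPEN_KERNEL.setflags(write=False)


# ----------------------------------------------------------------------
# activations
# ----------------------------------------------------------------------

def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def leaky_relu(x, alpha: float = 0.1):
    """x for x > 0, alpha*x otherwise. alpha must be non-negative."""
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, alpha * x)
    return out if out.ndim else float(out)


def swish(x):
    """Self-gated activation x * sigmoid(x) (gating slope fixed at 1)."""
    x = np.asarray(x, dtype=float)
    out = x * sigmoid(x)
    return out if out.ndim else float(out)


def _softplus(x):
    # ln(1 + e^x), overflow-safe for large |x|
    return np.logaddexp(0.0, x)


def mish(x):
    """x * tanh(softplus(x)); smooth, non-monotonic, slightly negative dip."""
    x = np.asarray(x, dtype=float)
    out = x * np.tanh(_softplus(x))
    return out if out.ndim else float(out)


def _relu_grad(x):
    return (x > 0).astype(x.dtype)


def _leaky_relu_grad(x, alpha=0.1):
    return np.where(x > 0, 1.0, alpha)


def _swish_grad(x):
    s = sigmoid(x)
    return s + x * s * (1.0 - s)


def _mish_grad(x):
    sp = _softplus(x)
    t = np.tanh(sp)
    return t + x * (1.0 - t * t) * sigmoid(x)


_ACTIVATIONS = {
    "relu": (relu, _relu_grad),
    "lrelu": (lambda x: leaky_relu(x, 0.1), lambda x: _leaky_relu_grad(x, 0.1)),
    "swish": (swish, _swish_grad),
    "mish": (mish, _mish_grad),
}


def activation(name: str, x):
    """Apply a named activation (relu / lrelu / swish / mish) elementwise."""
    try:
        fn, _ = _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None
    return fn(x)


def activation_grad(name: str, x):
    """Elementwise derivative of the named activation, evaluated at x."""
    try:
        _, g = _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None
    return g(np.asarray(x, dtype=float))


# ----------------------------------------------------------------------
# sharpening skip convolution
# ----------------------------------------------------------------------

def _conv2d_same_single(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution (flip-and-slide) with zero padding, one channel."""
    h, w = channel.shape
    pad = np.zeros((h + 2, w + 2), dtype=channel.dtype)
    pad[1:-1, 1:-1] = channel
    kf = kernel[::-1, ::-1]
    out = np.zeros_like(channel)
    for di in range(3):
        for dj in range(3):
            out += kf[di, dj] * pad[di : di + h, dj : dj + w]
    return out


def sharpen_features(feature_map: np.ndarray) -> np.ndarray:
    """Depthwise convolution of every channel with the fixed sharpening mask.

    Accepts (H, W), (H, W, C) or (N, H, W, C) arrays; zero padding keeps the
    spatial size. The kernel is symmetric and fixed, so this introduces no
    trainable parameters and no channel mixing.
    """
    fm = np.asarray(feature_map, dtype=float)
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[:, :, None]
    if fm.ndim == 3:
        fm = fm[None]
        batched = False
    elif fm.ndim == 4:
        batched = True
    else:
        raise ValueError(f"expected 2-4 dims, got shape {feature_map.shape}")
    n, h, w, c = fm.shape
    if h < 3 or w < 3:
        raise ValueError(f"spatial dims must be >= 3, got {h}x{w}")
    out = np.empty_like(fm)
    for i in range(n):
        for ch in range(c):
            out[i, :, :, ch] = _conv2d_same_single(fm[i, :, :, ch], SHARPEN_KERNEL)
    if not batched:
        out = out[0]
    if squeeze:
        out = out[:, :, 0]
    return out


# ----------------------------------------------------------------------
# attention gate (functional form)
# ----------------------------------------------------------------------

def attention_gate(
    x: np.ndarray,
    g: np.ndarray,
    w_x: np.ndarray,
    w_g: np.ndarray,
    w_s: np.ndarray,
    gate_activation: str = "swish",
):
    """Additive attention gate over a skip connection.

    The skip features ``x`` (H, W, Cx) and the gating signal ``g`` (H, W, Cg,
    already at the same spatial scale) are projected by 1x1 channel-wise
    convolutions ``w_x`` (Cx, Ci) and ``w_g`` (Cg, Ci), summed, passed through
    the gate activation (swish by default) and collapsed by ``w_s`` (Ci, 1)
    into a single sigmoid coefficient per location in (0, 1). Both bias terms
    are fixed at zero. Returns ``(x * coefficients, coefficients)``.
    """
    x = np.atleast_3d(np.asarray(x, dtype=float))
    g = np.atleast_3d(np.asarray(g, dtype=float))
    if x.shape[:2] != g.shape[:2]:
        raise ValueError(
            f"spatial mismatch between skip {x.shape[:2]} and gate {g.shape[:2]}"
        )
    w_x = np.atleast_2d(np.asarray(w_x, dtype=float))
    w_g = np.atleast_2d(np.asarray(w_g, dtype=float))
    w_s = np.asarray(w_s, dtype=float).reshape(w_x.shape[1], -1)
    pre = x @ w_x + g @ w_g  # (H, W, Ci); biases fixed at 0
    coeff = sigmoid(activation(gate_activation, pre) @ w_s)  # (H, W, 1)
    return x * coeff, coeff


# ----------------------------------------------------------------------
# loss family
# ----------------------------------------------------------------------

def _check_pair(y_true, y_pred):
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs prediction {p.shape}")
    return y, p


def bce_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Mean binary cross-entropy over all pixels, with probability clipping."""
    y, p = _check_pair(y_true, y_pred)
    p = np.clip(p, cfg.epsilon_log, 1.0 - cfg.epsilon_log)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_coefficient(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Soft Dice overlap (2*sum(y*p) + eps) / (sum(y) + sum(p) + eps).

    On binary inputs this is the set-based Dice 2|A∩B|/(|A|+|B|). The
    epsilon in the numerator makes the degenerate all-background case
    (empty truth, empty prediction) score 1 rather than 0.
    """
    y, p = _check_pair(y_true, y_pred)
    inter = float(np.sum(y * p))
    denom = float(np.sum(y) + np.sum(p))
    return (2.0 * inter + cfg.epsilon_dice) / (denom + cfg.epsilon_dice)


def dice_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    return 1.0 - dice_coefficient(y_true, y_pred, cfg)


def bce_dice_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Compound loss: binary cross-entropy plus (1 - soft Dice)."""
    return bce_loss(y_true, y_pred, cfg) + dice_loss(y_true, y_pred, cfg)


def bce_dice_grad(y_true, y_pred, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Analytic gradient of bce_dice_loss with respect to the predictions.

    Used to seed backpropagation during training; the forward loss above is
    the quantity it differentiates (probabilities evaluated at their clipped
    values, soft-Dice sums pooled over the whole array).
    """
    y, p = _check_pair(y_true, y_pred)
    n = p.size
    pc = np.clip(p, cfg.epsilon_log, 1.0 - cfg.epsilon_log)
    g_bce = (-(y / pc) + (1.0 - y) / (1.0 - pc)) / n
    inter = float(np.sum(y * p))
    denom = float(np.sum(y) + np.sum(p)) + cfg.epsilon_dice
    num = 2.0 * inter + cfg.epsilon_dice
    # d(1 - D)/dp_i with D = num/denom
    g_dice = -(2.0 * y * denom - num) / (denom * denom)
    return g_bce + g_dice
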