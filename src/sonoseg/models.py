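"""The four U-shaped segmentation architectures.

All variants share one encoder/decoder backbone: `depth` encoder blocks of
two 3x3 convolutions + activation + dropout, 2x2 max-pooling between levels,
a bottleneck block, and a decoder of 2x2 transposed-convolution upsampling,
a skip merge, two 3x3 convolutions + activation and dropout, finished by a
1x1 convolution with a sigmoid head. The variants differ only in the skip
merge:

- ``unet``: concatenate the raw encoder features.
- ``sharp_unet``: concatenate encoder features convolved with the fixed
  sharpening kernel — except the deepest skip, which stays unsharpened.
- ``attention_unet``: concatenate attention-gated encoder features, gated by
  the transposed-convolution output at the same scale.
- ``sharp_attention_unet``: concatenate BOTH the attention-gated and the
  sharpened encoder features with the upsampled decoder features (the
  deepest-skip sharpening exception is retained).

Dropout rates follow the 0.1 (encoder) / 0.5 (decoder) placement; the
bottleneck uses the encoder rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

VARIANTS = ("unet", "sharp_unet", "attention_unet", "sharp_attention_unet")
ACTIVATIONS = ("relu", "lrelu", "swish", "mish")


@dataclass
class ModelConfig:
    variant: str = "sharp_attention_unet"
    input_size: int = 128
    in_channels: int = 1
    depth: int = 4
    base_filters: int = 32
    activation: str = "swish"
    gate_activation: str = "swish"  # sigma_1 inside the attention gate
    dropout_encoder: float = 0.1
    dropout_decoder: float = 0.5
    sharpen_deepest_skip: bool = False
    gate_sharpened: bool = False  # feed sharpened (not raw) features to the AG
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.gate_activation not in ACTIVATIONS:
            raise ValueError(f"gate_activation must be one of {ACTIVATIONS}")
        if self.input_size % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={1 << self.depth}"
            )
        for name in ("dropout_encoder", "dropout_decoder"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0,1), got {v}")


@dataclass
class ModelSummary:
    trainable_parameter_count: int
    layers: list = field(default_factory=list)  # (name, shape) per parameter block
    output_shape: tuple = ()

    @property
    def attention_gate_count(self) -> int:
        return sum(1 for name, _ in self.layers if name.startswith("ag")) // 3


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    if len(shape) == 4:  # (kh, kw, cin, cout)
        rf = shape[0] * shape[1]
        fan_in, fan_out = rf * shape[2], rf * shape[3]
    else:
        fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class SegmentationModel:
    """A built network: parameters plus a define-by-run forward pass."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._build()

    # -- construction --------------------------------------------------
    def _add(self, rng, name, shape, zero=False):
        dtype = np.dtype(self.config.dtype)
        data = np.zeros(shape, dtype=dtype) if zero else _glorot(rng, shape, dtype)
        self.params[name] = ad.parameter(data, name=name)

    def _build(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        c_in = cfg.in_channels
        for lvl in range(cfg.depth):
            c_out = f << lvl
            self._add(rng, f"enc{lvl}_conv1_w", (3, 3, c_in, c_out))
            self._add(rng, f"enc{lvl}_conv1_b", (c_out,), zero=True)
            self._add(rng, f"enc{lvl}_conv2_w", (3, 3, c_out, c_out))
            self._add(rng, f"enc{lvl}_conv2_b", (c_out,), zero=True)
            c_in = c_out
        c_bot = f << cfg.depth
        self._add(rng, "bott_conv1_w", (3, 3, c_in, c_bot))
        self._add(rng, "bott_conv1_b", (c_bot,), zero=True)
        self._add(rng, "bott_conv2_w", (3, 3, c_bot, c_bot))
        self._add(rng, "bott_conv2_b", (c_bot,), zero=True)
        c_prev = c_bot
        for lvl in reversed(range(cfg.depth)):
            c_skip = f << lvl
            self._add(rng, f"dec{lvl}_up_w", (2, 2, c_prev, c_skip))
            self._add(rng, f"dec{lvl}_up_b", (c_skip,), zero=True)
            if cfg.variant in ("attention_unet", "sharp_attention_unet"):
                inter = max(c_skip // 2, 1)
                self._add(rng, f"ag{lvl}_wx", (1, 1, c_skip, inter))
                self._add(rng, f"ag{lvl}_wg", (1, 1, c_skip, inter))
                self._add(rng, f"ag{lvl}_ws", (1, 1, inter, 1))
            merged = self._merge_width(c_skip)
            self._add(rng, f"dec{lvl}_conv1_w", (3, 3, merged, c_skip))
            self._add(rng, f"dec{lvl}_conv1_b", (c_skip,), zero=True)
            self._add(rng, f"dec{lvl}_conv2_w", (3, 3, c_skip, c_skip))
            self._add(rng, f"dec{lvl}_conv2_b", (c_skip,), zero=True)
            c_prev = c_skip
        self._add(rng, "head_w", (1, 1, c_prev, 1))
        self._add(rng, "head_b", (1,), zero=True)

    def _merge_width(self, c_skip: int) -> int:
        # upsampled decoder features + one or two skip branches
        if self.config.variant == "sharp_attention_unet":
            return 3 * c_skip
        return 2 * c_skip

    # -- forward --------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Map an image batch (N, H, W, C) to a probability-map Tensor."""
        cfg = self.config
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4:
            raise ValueError(f"expected (N, H, W, C) batch, got shape {x.shape}")
        if x.shape[1] != cfg.input_size or x.shape[2] != cfg.input_size:
            raise ValueError(
                f"spatial size {x.shape[1]}x{x.shape[2]} does not match "
                f"model input_size {cfg.input_size}"
            )
        p = self.params
        t = ad.constant(x)
        skips: list[Tensor] = []
        for lvl in range(cfg.depth):
            t = self._block(t, f"enc{lvl}", cfg.dropout_encoder, training, rng)
            skips.append(t)
            t = ad.maxpool2x2(t)
        t = self._block(t, "bott", cfg.dropout_encoder, training, rng)
        for lvl in reversed(range(cfg.depth)):
            up = ad.conv_transpose2x2(t, p[f"dec{lvl}_up_w"], p[f"dec{lvl}_up_b"])
            t = ad.concat([up, *self._skip_branches(skips[lvl], up, lvl)])
            t = self._block(t, f"dec{lvl}", cfg.dropout_decoder, training, rng)
        return ad.sigmoid_t(ad.conv2d(t, p["head_w"], p["head_b"]))

    def _block(self, t, key, rate, training, rng):
        p = self.params
        t = ad.act(ad.conv2d(t, p[f"{key}_conv1_w"], p[f"{key}_conv1_b"]),
                   self.config.activation)
        t = ad.act(ad.conv2d(t, p[f"{key}_conv2_w"], p[f"{key}_conv2_b"]),
                   self.config.activation)
        return ad.dropout(t, rate, rng, training)

    def _skip_branches(self, skip: Tensor, up: Tensor, lvl: int) -> list[Tensor]:
        cfg = self.config
        deepest = lvl == cfg.depth - 1
        may_sharpen = cfg.sharpen_deepest_skip or not deepest
        if cfg.variant == "unet":
            return [skip]
        if cfg.variant == "sharp_unet":
            return [ad.sharpen(skip) if may_sharpen else skip]
        sharpened = ad.sharpen(skip) if may_sharpen else skip
        gate_input = sharpened if cfg.gate_sharpened else skip
        gated = self._attention_gate(gate_input, up, lvl)
        if cfg.variant == "attention_unet":
            return [gated]
        return [gated, sharpened]  # sharp_attention_unet

    def _attention_gate(self, skip: Tensor, gate: Tensor, lvl: int) -> Tensor:
        p = self.params
        pre = ad.add(
            ad.conv2d(skip, p[f"ag{lvl}_wx"]),
            ad.conv2d(gate, p[f"ag{lvl}_wg"]),
        )  # bias terms fixed at zero
        coeff = ad.sigmoid_t(
            ad.conv2d(ad.act(pre, self.config.gate_activation), p[f"ag{lvl}_ws"])
        )
        return ad.mul(skip, coeff)

    # -- introspection & persistence -----------------------------------
    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise ValueError(f"state dict missing parameters: {sorted(missing)}")
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype).reshape(v.data.shape)

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the ModelConfig."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build_model(config: ModelConfig) -> SegmentationModel:
    """Build one of the four variants from its configuration."""
    return SegmentationModel(config)


def summarize(model: SegmentationModel) -> ModelSummary:
    cfg = model.config
    return ModelSummary(
        trainable_parameter_count=model.parameter_count(),
        layers=[(k, tuple(v.data.shape)) for k, v in model.params.items()],
        output_shape=(cfg.input_size, cfg.input_size, 1),
    )
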