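"""Stochastic training-time augmentation applied identically to image and mask.

The policy mirrors common ultrasound practice: modest random rotation, zoom,
horizontal flip, width/height shifts, shear and a narrow brightness jitter —
strong geometric or photometric distortion would destroy diagnostically
meaningful texture. Geometric components act on image and mask about the
image centre (bilinear for the image, nearest-neighbour for the mask, empty
borders filled with 0); brightness is a multiplicative factor on the image
only, clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import warp

from .imaging import SegSample

__all__ = ["AugmentConfig", "TransformParams", "sample_params", "apply_transform"]


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the augmentation policy; each draw is uniform in its range.

    Zoom z means a scale factor of 1 + z; shear is a dimensionless shear
    factor; shifts are fractions of the image width/height.
    """

    rotation_range_deg: tuple[float, float] = (-45.0, 45.0)
    zoom_range: tuple[float, float] = (-0.08, 0.08)
    horizontal_flip: bool = True
    width_shift: float = 0.15
    height_shift: float = 0.15
    shear_range: tuple[float, float] = (-0.03, 0.03)
    brightness_range: tuple[float, float] = (0.99, 1.07)

    def __post_init__(self) -> None:
        for name in ("rotation_range_deg", "zoom_range", "shear_range",
                     "brightness_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high, got ({lo}, {hi})")
        if self.width_shift < 0 or self.height_shift < 0:
            raise ValueError("shift fractions must be >= 0")


@dataclass(frozen=True)
class TransformParams:
    """One concrete draw from the augmentation policy."""

    angle_deg: float = 0.0
    zoom: float = 0.0
    flip: bool = False
    dx: float = 0.0  # horizontal shift, fraction of width
    dy: float = 0.0  # vertical shift, fraction of height
    shear: float = 0.0
    brightness: float = 1.0

    def is_identity_geometry(self) -> bool:
        return (
            self.angle_deg == 0.0
            and self.zoom == 0.0
            and self.dx == 0.0
            and self.dy == 0.0
            and self.shear == 0.0
        )


def sample_params(config: AugmentConfig, rng_state) -> TransformParams:
    """Draw each transform parameter uniformly from its configured range."""
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    return TransformParams(
        angle_deg=float(rng.uniform(*config.rotation_range_deg)),
        zoom=float(rng.uniform(*config.zoom_range)),
        flip=bool(rng.random() < 0.5) if config.horizontal_flip else False,
        dx=float(rng.uniform(-config.width_shift, config.width_shift)),
        dy=float(rng.uniform(-config.height_shift, config.height_shift)),
        shear=float(rng.uniform(*config.shear_range)),
        brightness=float(rng.uniform(*config.brightness_range)),
    )


def _forward_matrix(params: TransformParams, shape: tuple[int, int]) -> np.ndarray:
    """Homogeneous (x, y) matrix mapping input pixels to output pixels:
    rotate, shear, zoom about the image centre, then translate."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    th = np.deg2rad(params.angle_deg)
    s = 1.0 + params.zoom
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    shr = np.array([[1, params.shear, 0], [0, 1, 0], [0, 0, 1]])
    zoom = np.diag([s, s, 1.0])
    to_c = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]])
    from_c = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]])
    shift = np.array(
        [[1, 0, params.dx * w], [0, 1, params.dy * h], [0, 0, 1]]
    )
    return shift @ from_c @ rot @ shr @ zoom @ to_c


def apply_transform(sample: SegSample, params: TransformParams) -> SegSample:
    """Apply one parameter draw to an image/mask pair.

    The horizontal flip is an exact axis reversal (applied first), so a
    flip-only transform is bit-exact and self-inverse; the remaining affine
    part is skipped entirely when it is the identity.
    """
    if not all(
        np.isfinite(v)
        for v in (params.angle_deg, params.zoom, params.dx, params.dy,
                  params.shear, params.brightness)
    ):
        raise ValueError("transform parameters must be finite")
    image = sample.image
    mask = sample.mask
    if params.flip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if params.is_identity_geometry():
        image = image.copy()
        mask = mask.copy()
    else:
        fwd = _forward_matrix(params, image.shape)
        inv = np.linalg.inv(fwd)
        image = warp(
            image, inv, order=1, mode="constant", cval=0.0, preserve_range=True
        )
        mask = warp(
            mask.astype(float), inv, order=0, mode="constant", cval=0.0,
            preserve_range=True,
        )
    if params.brightness != 1.0:
        image = np.clip(image * params.brightness, 0.0, 1.0)
    return SegSample(
        image=image,
        mask=(mask >= 0.5).astype(np.uint8),
        class_label=sample.class_label,
        identifier=sample.identifier,
    )
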