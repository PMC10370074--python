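"""Synthetic speckle-phantom generator with ground-truth lesion masks.

Emulates the appearance that matters for training and evaluating the
segmentation models: a speckle-textured grayscale background (multiplicative
gamma noise smoothed with a small Gaussian kernel) containing at most one
hypoechoic (darker-than-background) lesion. Benign lesions are smooth
ellipses; malignant lesions get an irregular, jagged boundary via a radial
sinusoidal perturbation. Normal phantoms carry an all-zero mask. Datasets
are written to disk in the class-subfolder PNG layout that
:func:`sonoseg.imaging.load_busi_dir` reads back, so the whole pipeline runs
without any external download.

Generation is a pure function of (config, class label, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import CLASS_LABELS, SegSample, write_gray_png, write_mask_png

__all__ = ["PhantomConfig", "make_phantom", "make_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom generator.

    lesion_radius_range is a fraction of the image width (semi-axis); the
    intensity drop is the fractional darkening inside the lesion relative to
    the surrounding tissue; speckle_shape is the gamma shape parameter of the
    multiplicative noise (larger = milder texture).
    """

    image_size: int = 128
    class_probabilities: tuple[float, float, float] = (0.17, 0.56, 0.27)
    lesion_radius_range: tuple[float, float] = (0.08, 0.30)
    lesion_intensity_drop: tuple[float, float] = (0.4, 0.7)
    boundary_blur_sigma: float = 1.5
    speckle_shape: float = 4.0
    speckle_smooth_sigma: float = 0.7
    shadow_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(
                f"lesion_radius_range must lie within (0, 0.5), got {self.lesion_radius_range}"
            )
        dlo, dhi = self.lesion_intensity_drop
        if not (0.0 <= dlo <= dhi <= 1.0):
            raise ValueError("lesion_intensity_drop must be an ordered pair in [0,1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not all(0.0 <= p <= 1.0 for p in self.class_probabilities):
            raise ValueError("class probabilities must lie in [0,1]")


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def draw_class(config: PhantomConfig, rng_state) -> str:
    """Sample a class label from the configured class mix."""
    rng = _as_rng(rng_state)
    p = np.asarray(config.class_probabilities, dtype=float)
    return str(rng.choice(CLASS_LABELS, p=p / p.sum()))


def _lesion_mask(config: PhantomConfig, rng: np.random.Generator, malignant: bool):
    """Filled-ellipse mask; malignant boundaries get sinusoidal jaggedness."""
    size = config.image_size
    lo, hi = config.lesion_radius_range
    a, b = rng.uniform(lo, hi, size=2) * size  # semi-axes, pixels
    amp = rng.uniform(0.12, 0.28) if malignant else 0.0
    margin = max(a, b) * (1.0 + amp) + 2.0 * config.boundary_blur_sigma + 1.0
    if 2 * margin >= size:
        raise ValueError(
            f"lesion_radius_range {config.lesion_radius_range} does not fit in a "
            f"{size}px image"
        )
    cx = rng.uniform(margin, size - margin)
    cy = rng.uniform(margin, size - margin)
    theta = rng.uniform(0.0, np.pi)
    lobes = int(rng.integers(5, 10)) if malignant else 0
    phase = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    rho = np.hypot(u / a, v / b)  # 1.0 on the unperturbed boundary
    if malignant:
        ang = np.arctan2(v / b, u / a)
        boundary = 1.0 + amp * np.sin(lobes * ang + phase)
    else:
        boundary = 1.0
    return (rho <= boundary).astype(np.uint8)


def make_phantom(config: PhantomConfig, class_label: str, rng_state) -> SegSample:
    """Generate one speckled phantom and its ground-truth mask.

    Deterministic given (config, class_label, rng_state); pass an integer
    seed or a ``numpy.random.Generator``.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(
            f"class_label must be one of {CLASS_LABELS}, got {class_label!r}"
        )
    rng = _as_rng(rng_state)
    size = config.image_size
    # smooth tissue background with mild large-scale intensity variation
    base = 0.55 + 0.08 * gaussian_filter(
        rng.standard_normal((size, size)), sigma=size / 6.0
    )
    # multiplicative speckle: unit-mean gamma noise, lightly smoothed
    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, (size, size))
    if config.speckle_smooth_sigma > 0:
        speckle = gaussian_filter(speckle, config.speckle_smooth_sigma)
    img = base * speckle
    if class_label == "normal":
        mask = np.zeros((size, size), dtype=np.uint8)
    else:
        mask = _lesion_mask(config, rng, malignant=class_label == "malignant")
        drop = rng.uniform(*config.lesion_intensity_drop)
        soft = gaussian_filter(mask.astype(float), config.boundary_blur_sigma)
        img = img * (1.0 - drop * soft)
        if config.shadow_enabled:
            # faint posterior shadow under the lesion columns
            profile = soft.max(axis=0)
            rows = np.arange(size)[:, None]
            below = rows > np.argmax(soft, axis=0)[None, :]
            img = img * (1.0 - 0.15 * profile[None, :] * below)
    img = np.clip(img, 0.0, 1.0)
    return SegSample(img, mask, class_label, identifier=class_label)


def make_dataset(
    config: PhantomConfig,
    n_normal: int,
    n_benign: int,
    n_malignant: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a phantom dataset to ``out_dir`` in the class-subfolder layout.

    Files are ``<class>/<class> (k).png`` with ``<class>/<class> (k)_mask.png``
    alongside. Returns (and writes as ``manifest.csv``) a manifest with one
    row per sample: identifier, class, image path, mask path.
    """
    for name, n in (("n_normal", n_normal), ("n_benign", n_benign),
                    ("n_malignant", n_malignant)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    counts = {"normal": n_normal, "benign": n_benign, "malignant": n_malignant}
    for label in CLASS_LABELS:
        cls_dir = out_dir / label
        if counts[label]:
            cls_dir.mkdir(exist_ok=True)
        for k in range(1, counts[label] + 1):
            sample = make_phantom(config, label, rng)
            stem = f"{label} ({k})"
            img_path = cls_dir / f"{stem}.png"
            mask_path = cls_dir / f"{stem}_mask.png"
            write_gray_png(img_path, sample.image)
            write_mask_png(mask_path, sample.mask)
            rows.append(
                {
                    "identifier": stem,
                    "class": label,
                    "image_path": str(img_path.relative_to(out_dir)),
                    "mask_path": str(mask_path.relative_to(out_dir)),
                }
            )
    manifest = pd.DataFrame(rows, columns=["identifier", "class", "image_path", "mask_path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
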