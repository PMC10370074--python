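"""Image / mask I/O, the BUSI directory dialect, resizing, and CLAHE.

Images are 8-bit grayscale PNG on disk and float arrays in [0, 1] in memory;
masks are {0, 255} PNG on disk and {0, 1} uint8 arrays in memory. A dataset
directory contains one subfolder per class (``normal``/``benign``/
``malignant``), each holding ``<class> (k).png`` images and one or more
``<class> (k)_mask*.png`` mask files; multiple masks for one image are merged
by pixel-wise union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure
from skimage.transform import resize as sk_resize

logger = logging.getLogger(__name__)

CLASS_LABELS = ("normal", "benign", "malignant")


@dataclass
class SegSample:
    """One grayscale image with its binary lesion mask and class label."""

    image: np.ndarray  # float, [0, 1], (H, W)
    mask: np.ndarray  # uint8, {0, 1}, same shape
    class_label: str
    identifier: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.identifier}: image {self.image.shape} and mask "
                f"{self.mask.shape} shapes differ"
            )
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.identifier}: mask values {vals} not in {{0,1}}")


@dataclass(frozen=True)
class ClaheConfig:
    """Contrast-limited adaptive histogram equalization settings.

    The clip limit is derived from the tile area M, the number of grey
    levels N, the clip factor alpha (percent) and the maximum tolerable
    histogram slope s_max as ``beta = (M / N) * (1 + alpha/100 * (s_max - 1))``
    — the maximum pixel count any histogram bin of a tile may hold before the
    excess is redistributed. ``tile_area`` may be left None, in which case it
    is derived from the image size and ``tile_grid`` when CLAHE is applied.
    """

    tile_area: int | None = None  # M, pixels per contextual tile
    n_gray_levels: int = 256  # N
    clip_factor: float = 2.0  # alpha, percent in [0, 100]
    max_slope: float = 4.0  # s_max, >= 1
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError(f"n_gray_levels must be >= 2, got {self.n_gray_levels}")
        if not (0.0 <= self.clip_factor <= 100.0):
            raise ValueError(f"clip_factor must be in [0,100], got {self.clip_factor}")
        if self.max_slope < 1.0:
            raise ValueError(f"max_slope must be >= 1, got {self.max_slope}")


def clahe_clip_limit(config: ClaheConfig, tile_area: int | None = None) -> float:
    """Clip limit beta = (M/N) * (1 + alpha/100 * (s_max - 1)).

    ``tile_area`` overrides ``config.tile_area`` when given.
    """
    m = tile_area if tile_area is not None else config.tile_area
    if m is None:
        raise ValueError("tile_area is unset; pass it or set it on the config")
    if m <= 0:
        raise ValueError(f"tile_area must be positive, got {m}")
    return (m / config.n_gray_levels) * (
        1.0 + config.clip_factor / 100.0 * (config.max_slope - 1.0)
    )


def apply_clahe(img: np.ndarray, config: ClaheConfig = ClaheConfig()) -> np.ndarray:
    """Tile-wise contrast-limited equalization with bilinear tile blending.

    The per-tile histogram clip limit comes from ``clahe_clip_limit``;
    skimage's ``equalize_adapthist`` performs the tiling, clipping,
    redistribution and bilinear interpolation between neighbouring tiles.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    rows, cols = config.tile_grid
    h, w = img.shape
    if rows > h or cols > w:
        raise ValueError(
            f"tile grid {config.tile_grid} larger than image {img.shape}"
        )
    kernel = (max(h // rows, 1), max(w // cols, 1))
    m = config.tile_area if config.tile_area is not None else kernel[0] * kernel[1]
    beta = clahe_clip_limit(config, tile_area=m)
    # skimage's normalized clip_limit c maps to an absolute per-bin count
    # c * tile_area, so beta (a count) is passed as beta / M.
    out = exposure.equalize_adapthist(
        img,
        kernel_size=kernel,
        clip_limit=min(beta / m, 1.0),
        nbins=config.n_gray_levels,
    )
    return np.clip(out, 0.0, 1.0)


# ----------------------------------------------------------------------
# PNG / directory round-trip
# ----------------------------------------------------------------------

def read_gray_png(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG as floats in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def write_gray_png(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as a {0, 255} 8-bit PNG."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def _binarize_mask(arr: np.ndarray) -> np.ndarray:
    """Re-binarize a loaded mask at half of its maximum value."""
    peak = arr.max()
    if peak == 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    return (arr >= 0.5 * peak).astype(np.uint8)


def load_busi_dir(root: str | Path) -> list[SegSample]:
    """Load every image/mask pair from a class-subfolder dataset directory.

    The class label is the subfolder name; an image's masks are all files
    matching ``<stem>_mask*`` in the same folder, merged by union. An image
    without any mask file is an error.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    samples: list[SegSample] = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        label = cls_dir.name
        if label not in CLASS_LABELS:
            logger.warning("skipping unrecognised class folder %s", cls_dir)
            continue
        for img_path in sorted(cls_dir.glob("*.png")):
            if "_mask" in img_path.stem:
                continue
            mask_paths = sorted(cls_dir.glob(f"{img_path.stem}_mask*.png"))
            if not mask_paths:
                raise FileNotFoundError(f"no mask file found for image {img_path}")
            image = read_gray_png(img_path)
            mask = np.zeros(image.shape, dtype=np.uint8)
            for mp in mask_paths:
                part = _binarize_mask(read_gray_png(mp))
                if part.shape != image.shape:
                    raise ValueError(f"mask {mp} shape differs from image {img_path}")
                mask |= part
            samples.append(SegSample(image, mask, label, img_path.stem))
    if not samples:
        logger.warning("no samples found under %s", root)
    return samples


def resize_pair(sample: SegSample, size: int) -> SegSample:
    """Resize image (bilinear) and mask (bilinear then re-thresholded at 0.5)
    to a square ``size`` x ``size`` grid."""
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    image = sk_resize(
        sample.image, (size, size), order=1, preserve_range=True, anti_aliasing=True
    )
    mask_f = sk_resize(
        sample.mask.astype(float), (size, size), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return SegSample(
        image=np.clip(image, 0.0, 1.0),
        mask=(mask_f >= 0.5).astype(np.uint8),
        class_label=sample.class_label,
        identifier=sample.identifier,
    )
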