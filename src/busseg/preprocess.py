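"""Standardized network input: aspect-preserving resize with zero padding,
per-image standard scoring, and the two ultrasound-safe augmentations.

B-mode intensity depends on gain, voltage and transducer, so each image is
standard-scored (zero mean, unit standard deviation over the full padded
raster).  Augmentation is deliberately restricted to horizontal flipping and
equal-axis zooming: vertical flips, shears and anisotropic scaling would
destroy acoustic features (posterior shadowing direction, mass size and
aspect statistics) that carry diagnostic meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import BModeImage, SegmentationMask

__all__ = [
    "PreprocessConfig",
    "Placement",
    "resize_pad",
    "unmap",
    "standardize",
    "augment",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Target grid and augmentation ranges.

    target_size must be divisible by 16 so that four 2x down-poolings land on
    an integer grid.  zoom_range defaults to (0.9, 1.1) and flip_probability
    to 0.5; the transforms themselves are fixed, only their ranges are knobs.
    """

    target_size: int = 208
    zoom_range: tuple[float, float] = (0.9, 1.1)
    flip_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.target_size % 16 != 0:
            raise ValueError("target_size must be divisible by 16")
        lo, hi = self.zoom_range
        if not (0 < lo <= hi):
            raise ValueError("zoom_range must satisfy 0 < low <= high")
        if not (0.0 <= self.flip_probability <= 1.0):
            raise ValueError("flip_probability must be in [0, 1]")


@dataclass(frozen=True)
class Placement:
    """Where the content landed inside the padded square; inverts the mapping."""

    original_shape: tuple[int, int]
    content_shape: tuple[int, int]
    scale: float
    pad_top: int
    pad_left: int


def _as_array(image) -> np.ndarray:
    if isinstance(image, BModeImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def resize_pad(
    image,
    mask: SegmentationMask | np.ndarray | None = None,
    config: PreprocessConfig | int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, Placement]:
    """Downsample to ``target_size`` x ``target_size`` with zero padding.

    The longer dimension is scaled to ``target_size``; the shorter one is
    scaled by the same factor (preserving aspect ratio) and centered with
    zero padding, the extra row/column of an odd remainder going to the
    bottom/right.  Images are resampled bilinearly, masks nearest-neighbor
    (they stay strictly binary).  The returned :class:`Placement` lets
    predictions be mapped back onto the original grid with :func:`unmap`.

    ``config`` may be a bare integer target size for grids that are not
    network inputs (e.g. the unpadded comparator's 108x108 frame, which the
    divisible-by-16 invariant does not apply to).
    """
    if config is None:
        config = PreprocessConfig()
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("empty image")
    h, w = arr.shape
    t = config if isinstance(config, int) else config.target_size
    scale = t / max(h, w)
    ch, cw = max(1, round(h * scale)), max(1, round(w * scale))
    content = _sk_resize(
        arr.astype(np.float64), (ch, cw), order=1, anti_aliasing=(scale < 1),
        preserve_range=True,
    )
    pad_top = (t - ch) // 2
    pad_left = (t - cw) // 2
    out = np.zeros((t, t), dtype=np.float64)
    out[pad_top : pad_top + ch, pad_left : pad_left + cw] = content

    placement = Placement((h, w), (ch, cw), scale, pad_top, pad_left)

    out_mask = None
    if mask is not None:
        m = mask.pixels if isinstance(mask, SegmentationMask) else np.asarray(mask)
        if m.shape != (h, w):
            raise ValueError("mask shape does not match image shape")
        mc = _sk_resize(m.astype(float), (ch, cw), order=0, preserve_range=True)
        out_mask = np.zeros((t, t), dtype=np.uint8)
        out_mask[pad_top : pad_top + ch, pad_left : pad_left + cw] = (
            mc > 0.5
        ).astype(np.uint8)
    return out, out_mask, placement


def unmap(mask: np.ndarray, placement: Placement) -> np.ndarray:
    """Map a mask on the padded grid back to original-image coordinates."""
    m = np.asarray(mask)
    ch, cw = placement.content_shape
    content = m[
        placement.pad_top : placement.pad_top + ch,
        placement.pad_left : placement.pad_left + cw,
    ]
    back = _sk_resize(
        content.astype(float), placement.original_shape, order=0, preserve_range=True
    )
    return (back > 0.5).astype(np.uint8)


def standardize(raster: np.ndarray) -> np.ndarray:
    """Standard score: subtract the image mean, divide by its standard deviation.

    Applied to the full padded raster, zeros included.  A constant image has
    no scale; it maps to all zeros with a warning.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty raster")
    sd = arr.std()
    if sd == 0:
        warnings.warn("constant image: standard deviation is zero, returning zeros")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def _zoom_equal_axis(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom both axes by ``factor`` about the center, crop/pad back to shape."""
    h, w = arr.shape
    zh, zw = max(1, round(h * factor)), max(1, round(w * factor))
    zoomed = _sk_resize(
        arr.astype(np.float64), (zh, zw), order=order,
        anti_aliasing=(order == 1 and factor < 1), preserve_range=True,
    )
    out = np.zeros((h, w), dtype=np.float64)
    if factor >= 1.0:  # central crop
        top, left = (zh - h) // 2, (zw - w) // 2
        out[:, :] = zoomed[top : top + h, left : left + w]
    else:  # center with zero pad
        top, left = (h - zh) // 2, (w - zw) // 2
        out[top : top + zh, left : left + zw] = zoomed
    return out


def augment(
    raster: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random ultrasound-safe augmentation draw to an image/mask pair.

    With probability ``flip_probability`` both are mirrored left-right; a zoom
    factor drawn uniformly from ``zoom_range`` is applied identically to both
    axes (no aspect change), after which the raster is center-cropped or
    zero-padded back to its shape.  These are the only transforms this module
    exposes.
    """
    config = config or PreprocessConfig()
    rng = rng or np.random.default_rng()
    img = np.asarray(raster, dtype=np.float64)
    m = np.asarray(mask)
    if img.shape != m.shape:
        raise ValueError("raster and mask must share a shape")
    if rng.random() < config.flip_probability:
        img = img[:, ::-1].copy()
        m = m[:, ::-1].copy()
    factor = rng.uniform(*config.zoom_range)
    if factor <= 0:
        raise ValueError("zoom factor must be > 0")
    if factor != 1.0:
        img = _zoom_equal_axis(img, factor, order=1)
        m = (_zoom_equal_axis(m.astype(float), factor, order=0) > 0.5).astype(np.uint8)
    return img, m.astype(np.uint8)
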