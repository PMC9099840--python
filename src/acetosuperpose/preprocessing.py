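"""Acetowhite mask construction and geometric normalisation to 256x256.

The preprocessing pipeline has three steps, always applied in this order:

1. **mask construction** at native resolution — every pixel outside the
   annotated rectangle is set to exact black, pixels inside are copied
   bit-exactly (the mask keeps original intensities, it is not binary:
   the mask channels later serve as intensity sources for superposition);
2. **centre crop to a square** — cervigrams are landscape frames whose
   lateral thirds hold vaginal wall and speculum, so the longer axis is
   cropped symmetrically about the centre (odd remainders drop the extra
   column/row on the high-index side);
3. **bilinear resize** to the square training size (default 256).

Original and mask go through steps 2-3 with identical geometry so that
the annotation stays aligned between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .types import AnnotatedImage, Rect, ValidationError, check_raster

__all__ = [
    "MaskImage",
    "ProcessedPair",
    "make_acetowhite_mask",
    "center_crop_square",
    "crop_window",
    "resize_to_target",
    "transform_roi",
    "preprocess_pair",
]

TARGET_SIZE = 256


@dataclass
class MaskImage:
    """Acetowhite mask: source pixels inside the ROI, black outside."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = check_raster(self.pixels)


@dataclass
class ProcessedPair:
    """Original/mask rasters normalised to the square training size.

    ``roi`` carries the annotation rectangle mapped through the crop and
    resize, clipped to the output frame (None if it fell fully outside).
    """

    original: np.ndarray
    mask: np.ndarray
    label: str
    roi: Rect | None = None

    def __post_init__(self) -> None:
        self.original = check_raster(self.original, "original")
        self.mask = check_raster(self.mask, "mask")
        if self.original.shape != self.mask.shape:
            raise ValidationError(
                f"original and mask shapes differ: {self.original.shape} vs {self.mask.shape}"
            )


def make_acetowhite_mask(image: AnnotatedImage) -> MaskImage:
    """Black out everything outside the annotated acetowhite rectangle."""
    roi = image.roi
    roi.validate(image_width=image.width, image_height=image.height)
    out = np.zeros_like(image.pixels)
    out[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width] = image.pixels[
        roi.y : roi.y + roi.height, roi.x : roi.x + roi.width
    ]
    return MaskImage(pixels=out)


def crop_window(width: int, height: int) -> tuple[int, int, int]:
    """Return (x_offset, y_offset, side) of the centred square crop.

    The square side is ``min(width, height)``; the longer axis is cropped
    symmetrically, and an odd discard loses the extra column (or row) on
    the high-index side because the offset is the floor of half the
    discard.
    """
    side = min(width, height)
    x_off = (width - side) // 2
    y_off = (height - side) // 2
    return x_off, y_off, side


def center_crop_square(pixels: np.ndarray) -> np.ndarray:
    """Crop the longer axis symmetrically about the centre to a square."""
    pixels = check_raster(pixels)
    h, w = pixels.shape[:2]
    x_off, y_off, side = crop_window(w, h)
    return pixels[y_off : y_off + side, x_off : x_off + side]


def resize_to_target(pixels: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Bilinear-resize a square raster to ``size`` x ``size``."""
    pixels = check_raster(pixels)
    h, w = pixels.shape[:2]
    if h != w:
        raise ValidationError(f"resize expects a square raster, got {h}x{w}; crop first")
    if h == size:
        return pixels.copy()
    out = Image.fromarray(pixels).resize((size, size), Image.BILINEAR)
    return np.asarray(out)


def transform_roi(
    roi: Rect, image_width: int, image_height: int, size: int = TARGET_SIZE
) -> Rect | None:
    """Map an annotation rectangle through the centre crop and resize.

    The rectangle is clipped to the crop window first; returns None when
    it lies entirely outside. Output coordinates are rounded to pixels in
    the ``size`` x ``size`` frame.
    """
    x_off, y_off, side = crop_window(image_width, image_height)
    x0 = max(roi.x - x_off, 0)
    y0 = max(roi.y - y_off, 0)
    x1 = min(roi.x + roi.width - x_off, side)
    y1 = min(roi.y + roi.height - y_off, side)
    if x1 <= x0 or y1 <= y0:
        return None
    scale = size / side
    sx0 = int(round(x0 * scale))
    sy0 = int(round(y0 * scale))
    sx1 = min(max(int(round(x1 * scale)), sx0 + 1), size)
    sy1 = min(max(int(round(y1 * scale)), sy0 + 1), size)
    return Rect(x=sx0, y=sy0, width=sx1 - sx0, height=sy1 - sy0)


def preprocess_pair(image: AnnotatedImage, size: int = TARGET_SIZE) -> ProcessedPair:
    """Mask at native resolution, then crop and resize both rasters.

    The mask is built before any geometry change so annotation coordinates
    live in a single frame; crop and resize use identical offsets and the
    same bilinear interpolation for the original and the mask.
    """
    mask = make_acetowhite_mask(image)
    original = resize_to_target(center_crop_square(image.pixels), size=size)
    mask_out = resize_to_target(center_crop_square(mask.pixels), size=size)
    roi = transform_roi(image.roi, image.width, image.height, size=size)
    return ProcessedPair(original=original, mask=mask_out, label=image.label, roi=roi)
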