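"""Shared domain types: rectangles, annotated images, class labels.

Conventions used throughout the package:

* rasters are ``numpy.uint8`` arrays of shape ``(height, width, 3)`` in
  R, G, B channel order;
* rectangles are 0-based and half-open on both axes, i.e. a rectangle
  ``(x, y, w, h)`` covers columns ``x .. x+w-1`` and rows ``y .. y+h-1``;
* the two cervicography grades are ``"A1"`` (atypical, the negative /
  normal class) and ``"P1B"`` (dysplastic, the positive / abnormal class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Recognised class labels. P1B (dysplasia) is the positive class.
LABELS = ("A1", "P1B")
POSITIVE_LABEL = "P1B"


class ValidationError(ValueError):
    """Raised when a domain invariant is violated; names the offending field."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, 0-based, half-open on both axes."""

    x: int
    y: int
    width: int
    height: int

    def validate(self, image_width: int | None = None, image_height: int | None = None) -> None:
        if self.width <= 0:
            raise ValidationError(f"roi width must be positive, got {self.width}")
        if self.height <= 0:
            raise ValidationError(f"roi height must be positive, got {self.height}")
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"roi origin must be nonnegative, got ({self.x}, {self.y})")
        if image_width is not None and self.x + self.width > image_width:
            raise ValidationError(
                f"roi exceeds image width: x+width = {self.x + self.width} > {image_width}"
            )
        if image_height is not None and self.y + self.height > image_height:
            raise ValidationError(
                f"roi exceeds image height: y+height = {self.y + self.height} > {image_height}"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        """(cx, cy) centre of the covered pixel area."""
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


def check_raster(pixels: np.ndarray, name: str = "pixels") -> np.ndarray:
    """Validate a 3-channel 8-bit raster and return it."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError(
            f"{name} must have shape (height, width, 3), got {pixels.shape}"
        )
    if pixels.dtype != np.uint8:
        raise ValidationError(f"{name} must be 8-bit (uint8), got {pixels.dtype}")
    return pixels


def check_label(label: str) -> str:
    if label not in LABELS:
        raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
    return label


@dataclass
class AnnotatedImage:
    """A 3-channel 8-bit image with one rectangular acetowhite annotation.

    Attributes
    ----------
    pixels
        ``(height, width, 3)`` uint8 raster, R,G,B channel order.
    roi
        The annotated acetowhite rectangle, fully inside the image.
    label
        ``"A1"`` or ``"P1B"``.
    """

    pixels: np.ndarray
    roi: Rect
    label: str

    def __post_init__(self) -> None:
        self.pixels = check_raster(self.pixels)
        check_label(self.label)
        h, w = self.pixels.shape[:2]
        self.roi.validate(image_width=w, image_height=h)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]
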