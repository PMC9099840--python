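"""RGB channel superposition: the core recombination algorithm.

A superposition image is built by selecting one channel of the acetowhite
mask image (MR, MG or MB) and two distinct channels of the original image
(from OR, OG, OB) and placing the three selected single-channel planes
into the three RGB slots of a new image. No pixel arithmetic is performed:
the operation is pure plane selection and placement.

Slot assignment: every selected plane occupies the output slot of its own
channel identity. When the mask plane and one original plane share an
identity (e.g. MR together with OR), the mask plane keeps its native slot
and the displaced original plane takes the single remaining free slot.

With 3 mask-channel choices and 3 unordered original pairs this yields
exactly nine cases. Inside the annotated ROI the mask equals the original,
so ROI pixels carry information from all three selected original channels;
outside the ROI the mask plane is black, so background pixels carry only
two — the mechanism by which superposition concentrates information on the
acetowhite region while retaining peripheral context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .types import ValidationError, check_raster

__all__ = [
    "CHANNELS",
    "ChannelPlane",
    "ChannelCombo",
    "split_channels",
    "merge_channels",
    "enumerate_superposition_cases",
    "superpose",
    "superpose_dataset",
]

#: Channel identities in raster storage order.
CHANNELS = ("R", "G", "B")
_SLOT = {c: i for i, c in enumerate(CHANNELS)}

#: Unordered original-channel pairs in canonical row order:
#: (G,B), (G,R), (B,R) — i.e. "OG + OB", "OG + OR", "OB + OR".
_ORIGINAL_PAIRS = (("G", "B"), ("G", "R"), ("B", "R"))


@dataclass(frozen=True)
class ChannelPlane:
    """One single-channel plane tagged with its identity and source image."""

    identity: str  # R, G or B
    source: str  # "original" or "mask"
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.identity not in CHANNELS:
            raise ValidationError(f"channel identity must be R/G/B, got {self.identity!r}")
        if self.source not in ("original", "mask"):
            raise ValidationError(f"source must be 'original' or 'mask', got {self.source!r}")
        if np.asarray(self.pixels).ndim != 2:
            raise ValidationError("a channel plane must be a single-channel 2-D raster")


@dataclass(frozen=True)
class ChannelCombo:
    """One superposition case: a mask channel plus two original channels."""

    mask_channel: str
    original_channels: tuple[str, str]

    def __post_init__(self) -> None:
        if self.mask_channel not in CHANNELS:
            raise ValidationError(f"mask_channel must be R/G/B, got {self.mask_channel!r}")
        a, b = self.original_channels
        if a not in CHANNELS or b not in CHANNELS or a == b:
            raise ValidationError(
                f"original_channels must be two distinct identities, got {self.original_channels}"
            )

    @property
    def name(self) -> str:
        """Canonical name, mask channel first: e.g. ``"MR + OB + OR"``."""
        a, b = self.original_channels
        return f"M{self.mask_channel} + O{a} + O{b}"

    @classmethod
    def from_name(cls, name: str) -> "ChannelCombo":
        """Parse a canonical (or whitespace-sloppy) combo name."""
        parts = re.findall(r"[MO][RGB]", name.upper())
        masks = [p[1] for p in parts if p[0] == "M"]
        origs = [p[1] for p in parts if p[0] == "O"]
        if len(masks) != 1 or len(origs) != 2:
            raise ValidationError(
                f"combo name must contain one M-channel and two O-channels, got {name!r}"
            )
        pair = _canonical_pair(origs[0], origs[1])
        return cls(mask_channel=masks[0], original_channels=pair)


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    for pair in _ORIGINAL_PAIRS:
        if {a, b} == set(pair):
            return pair
    raise ValidationError(f"original channels must be two distinct of R/G/B, got {(a, b)}")


def split_channels(pixels: np.ndarray, source: str = "original") -> tuple[ChannelPlane, ChannelPlane, ChannelPlane]:
    """Split a 3-channel raster into its R, G and B planes."""
    pixels = check_raster(pixels)
    return tuple(
        ChannelPlane(identity=c, source=source, pixels=pixels[..., i].copy())
        for i, c in enumerate(CHANNELS)
    )


def merge_channels(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stack three single-channel planes back into an R,G,B raster."""
    return np.stack([r, g, b], axis=-1)


def enumerate_superposition_cases() -> list[ChannelCombo]:
    """All nine superposition cases in canonical row order.

    Mask channels iterate R, G, B; within each, the original pairs iterate
    (G,B), (G,R), (B,R), giving rows "MR + OG + OB" ... "MB + OB + OR".
    """
    return [
        ChannelCombo(mask_channel=m, original_channels=pair)
        for m in CHANNELS
        for pair in _ORIGINAL_PAIRS
    ]


def superpose(original: np.ndarray, mask: np.ndarray, combo: ChannelCombo) -> np.ndarray:
    """Compose a 3-channel image from the combo's selected planes.

    Pure selection/placement: each output slot is a bit-exact copy of one
    selected source plane. The mask plane always sits in its native slot;
    an original plane displaced by an identity collision moves to the one
    remaining free slot.
    """
    original = check_raster(original, "original")
    mask = check_raster(mask, "mask")
    if original.shape != mask.shape:
        raise ValidationError(
            f"original and mask dimensions differ: {original.shape} vs {mask.shape}"
        )
    out = np.empty_like(original)
    m = combo.mask_channel
    out[..., _SLOT[m]] = mask[..., _SLOT[m]]
    taken = {_SLOT[m]}
    collided = [c for c in combo.original_channels if c == m]
    for c in combo.original_channels:
        if c != m:
            out[..., _SLOT[c]] = original[..., _SLOT[c]]
            taken.add(_SLOT[c])
    for c in collided:
        free = ({0, 1, 2} - taken).pop()
        out[..., free] = original[..., _SLOT[c]]
        taken.add(free)
    return out


def superpose_dataset(pairs, combo: ChannelCombo) -> list[tuple[np.ndarray, str]]:
    """Apply one combo to every processed pair; labels and order preserved."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("superpose_dataset requires a nonempty collection")
    return [(superpose(p.original, p.mask, combo), p.label) for p in pairs]
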