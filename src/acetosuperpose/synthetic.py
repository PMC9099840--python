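"""Synthetic cervigram generator with rectangular acetowhite annotations.

Clinical cervicography datasets are private, so every downstream stage of
this package is exercised on synthetic images that emulate the relevant
gross properties of a cervigram:

* a 1504x1000 landscape frame whose centre holds a pinkish elliptical
  cervix disc with a dark external os in the middle;
* lateral vaginal-wall / speculum clutter bands on both sides, whose
  brightness varies image to image (a nuisance factor uncorrelated with
  class);
* one bright acetowhite patch inside the cervix: thin and translucent with
  an irregular border for grade A1, opaque with a regular border for grade
  P1B — the class signal is planted exclusively inside the annotated ROI;
* whole-image channel intensity mass ordered R > B > G, as observed on
  real cervigram histograms.

The generator is deterministic: identical parameters and seed give
bit-identical rasters, with per-image seeds derived from the master seed
and the image index through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image

from .types import AnnotatedImage, LABELS, Rect, ValidationError, check_label

__all__ = [
    "SyntheticParams",
    "generate_cervix_image",
    "generate_dataset",
    "iter_dataset",
    "write_annotations",
    "read_annotations",
    "write_dataset",
    "load_image",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic cervigram generator.

    Defaults reproduce the study conditions: 1504x1000 frames, 438 A1 and
    477 P1B images, a translucent A1 patch (opacity 0.35) versus an opaque
    P1B patch (opacity 0.65), and channel means ordered R > B > G.
    ``noise_sd`` is additive Gaussian pixel noise in 8-bit intensity units.
    """

    image_width: int = 1504
    image_height: int = 1000
    n_A1: int = 438
    n_P1B: int = 477
    acetowhite_opacity_A1: float = 0.35
    acetowhite_opacity_P1B: float = 0.65
    border_regularity_P1B: float = 0.85
    noise_sd: float = 8.0
    channel_means: tuple[float, float, float] = (185.0, 95.0, 135.0)  # (R, G, B)
    seed: int = 0

    # A1 borders are irregular/angled; kept fixed rather than exposed as a knob.
    _border_regularity_A1: float = field(default=0.30, repr=False)

    def validate(self) -> None:
        for name in ("image_width", "image_height", "n_A1", "n_P1B"):
            v = getattr(self, name)
            if name.startswith("image") and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
            if name.startswith("n_") and v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        for name in (
            "acetowhite_opacity_A1",
            "acetowhite_opacity_P1B",
            "border_regularity_P1B",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.acetowhite_opacity_P1B <= self.acetowhite_opacity_A1:
            raise ValidationError(
                "acetowhite_opacity_P1B must exceed acetowhite_opacity_A1 "
                f"({self.acetowhite_opacity_P1B} <= {self.acetowhite_opacity_A1})"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        r, g, b = self.channel_means
        if not (r > b > g):
            raise ValidationError(
                f"channel_means must be ordered R > B > G, got R={r}, G={g}, B={b}"
            )


def _ellipse_mask(
    yy: np.ndarray, xx: np.ndarray, cx: float, cy: float, rx: float, ry: float
) -> np.ndarray:
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def generate_cervix_image(
    params: SyntheticParams, label: str, seed: int
) -> AnnotatedImage:
    """Render one synthetic cervigram of the given class.

    The class signal lives inside the returned ROI: the acetowhite patch is
    blended toward white with a label-dependent opacity, and its border is
    jagged for A1 and regular for P1B. Everything else (clutter brightness,
    illumination, patch placement) varies with the seed but not the label.
    """
    params.validate()
    check_label(label)
    rng = np.random.default_rng(seed)
    h, w = params.image_height, params.image_width
    mr, mg, mb = params.channel_means
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    img = np.empty((h, w, 3), dtype=np.float32)
    # dark vaginal canal background, same hue ordering as the cervix
    img[..., 0] = mr * 0.22
    img[..., 1] = mg * 0.22
    img[..., 2] = mb * 0.22

    illum = float(rng.normal(1.0, 0.08))
    illum = min(max(illum, 0.7), 1.3)

    # cervix disc with radial shading
    ccx = w / 2 + rng.normal(0, w * 0.01)
    ccy = h / 2 + rng.normal(0, h * 0.01)
    crx = w * rng.uniform(0.26, 0.30)
    cry = h * rng.uniform(0.40, 0.46)
    r2 = ((xx - ccx) / crx) ** 2 + ((yy - ccy) / cry) ** 2
    cervix = r2 <= 1.0
    shade = (1.0 - 0.25 * np.clip(r2, 0, 1)).astype(np.float32)
    for c, mean in enumerate((mr, mg, mb)):
        img[..., c] = np.where(cervix, mean * shade * illum, img[..., c])

    # dark external os at the disc centre
    os_mask = _ellipse_mask(yy, xx, ccx, ccy, w * 0.025, h * 0.05)
    img[os_mask] *= 0.30

    # lateral speculum / vaginal-wall clutter bands: per-image nuisance
    for side in (0, 1):
        bw = int(w * rng.uniform(0.08, 0.14))
        gain = rng.uniform(0.5, 1.4)
        band = np.zeros((h, w), dtype=bool)
        if side == 0:
            band[:, :bw] = True
        else:
            band[:, w - bw :] = True
        band &= ~cervix
        streak = 1.0 + 0.2 * np.sin(yy / rng.uniform(20, 60) + rng.uniform(0, 6.28))
        col = np.array([mr * 0.55, mg * 0.50, mb * 0.52], dtype=np.float32) * gain
        for c in range(3):
            img[..., c] = np.where(band, col[c] * streak.astype(np.float32), img[..., c])

    # acetowhite patch: offset from the os, inside the cervix disc
    if label == "P1B":
        opacity = params.acetowhite_opacity_P1B
        regularity = params.border_regularity_P1B
    else:
        opacity = params.acetowhite_opacity_A1
        regularity = params._border_regularity_A1
    ang = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(0.30, 0.55)
    pcx = ccx + np.cos(ang) * crx * dist
    pcy = ccy + np.sin(ang) * cry * dist
    prx = w * rng.uniform(0.055, 0.075)
    pry = h * rng.uniform(0.09, 0.12)

    theta = np.arctan2(yy - pcy, xx - pcx)
    irregular = 1.0 - regularity
    wobble = (
        1.0
        + 0.30 * irregular * np.sin(3 * theta + rng.uniform(0, 6.28))
        + 0.18 * irregular * np.sin(7 * theta + rng.uniform(0, 6.28))
    )
    rad = np.sqrt(((xx - pcx) / prx) ** 2 + ((yy - pcy) / pry) ** 2)
    patch = rad <= wobble
    # translucent patches also feather toward the border
    alpha = np.where(patch, opacity * np.clip(1.6 - rad, 0.0, 1.0) ** 0.3, 0.0)
    alpha = alpha.astype(np.float32)[..., None]
    img = img * (1.0 - alpha) + 255.0 * alpha

    if params.noise_sd > 0:
        img = img + rng.standard_normal(img.shape, dtype=np.float32) * np.float32(params.noise_sd)
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    # rectangular ROI = bounding box of the patch plus a small margin
    ys, xs = np.nonzero(patch)
    margin = 4
    x0 = max(int(xs.min()) - margin, 0)
    x1 = min(int(xs.max()) + 1 + margin, w)
    y0 = max(int(ys.min()) - margin, 0)
    y1 = min(int(ys.max()) + 1 + margin, h)
    roi = Rect(x=x0, y=y0, width=x1 - x0, height=y1 - y0)
    return AnnotatedImage(pixels=pixels, roi=roi, label=label)


def _child_seed(master_seed: int, index: int) -> int:
    """Reproducible per-image seed derived from (master seed, image index)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def iter_dataset(params: SyntheticParams) -> Iterator[AnnotatedImage]:
    """Yield the dataset lazily: all A1 images first, then all P1B."""
    params.validate()
    labels = ["A1"] * params.n_A1 + ["P1B"] * params.n_P1B
    for index, label in enumerate(labels):
        yield generate_cervix_image(params, label, _child_seed(params.seed, index))


def generate_dataset(params: SyntheticParams) -> list[AnnotatedImage]:
    """Materialise the full dataset (n_A1 + n_P1B annotated images)."""
    return list(iter_dataset(params))


# ---------------------------------------------------------------------------
# annotation and image I/O


def write_annotations(dataset, path, filenames=None) -> None:
    """Write one JSON record per image: file, image size, ROI and label.

    Records are JSON lines ``{"file", "image_width", "image_height",
    "x", "y", "w", "h", "label"}`` with 0-based half-open rectangles.
    """
    path = Path(path)
    if filenames is None:
        filenames = [f"img_{i:05d}.png" for i in range(len(dataset))]
    with path.open("w") as fh:
        for img, fname in zip(dataset, filenames):
            rec = {
                "file": fname,
                "image_width": img.width,
                "image_height": img.height,
                "x": img.roi.x,
                "y": img.roi.y,
                "w": img.roi.width,
                "h": img.roi.height,
                "label": img.label,
            }
            fh.write(json.dumps(rec) + "\n")


def read_annotations(path) -> list[dict]:
    """Read JSON-lines annotations, enforcing the in-bounds ROI invariant.

    Returns a list of dicts with keys ``file``, ``roi`` (:class:`Rect`) and
    ``label``. Malformed lines raise a parse error naming the line number.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                roi = Rect(
                    x=int(rec["x"]), y=int(rec["y"]),
                    width=int(rec["w"]), height=int(rec["h"]),
                )
                label = check_label(rec["label"])
                roi.validate(
                    image_width=int(rec["image_width"]),
                    image_height=int(rec["image_height"]),
                )
            except ValidationError:
                raise
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed annotation at line {lineno}: {exc}") from exc
            records.append({"file": rec["file"], "roi": roi, "label": label})
    return records


def write_dataset(dataset, out_dir, annotations_name: str = "annotations.jsonl") -> Path:
    """Write images as lossless PNGs plus a JSON-lines annotation file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filenames = [f"img_{i:05d}.png" for i in range(len(dataset))]
    for img, fname in zip(dataset, filenames):
        Image.fromarray(img.pixels).save(out_dir / fname)
    ann_path = out_dir / annotations_name
    write_annotations(dataset, ann_path, filenames=filenames)
    return ann_path


def load_image(path) -> np.ndarray:
    """Read a PNG or JPEG file as an RGB uint8 raster."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
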