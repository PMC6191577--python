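"""Green-pixel segmentation of canopy photographs in HSB color space.

Canopy cover of young cereal stands is scored by classifying each pixel of a
nadir RGB photograph as plant (green) or background (soil, dead material)
using fixed thresholds in the hue–saturation–brightness (HSB = HSV) space,
then reporting

    green pixels (%) = green pixel count / total pixel count * 100.

All three HSB channels are expressed as bytes on the 0–255 scale — the
ImageJ color-threshold convention.  The default green band is hue 45–120 on
that byte scale (≈ 63.5°–169.4°), with saturation and brightness unrestricted.
Note that many other stacks express hue in degrees [0, 360) or floats [0, 1];
thresholds taken from elsewhere must be converted to the byte scale first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "HSBThresholds",
    "GreenPixelResult",
    "rgb_to_hsb",
    "segment_green",
    "green_fraction",
    "batch_green_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HSBThresholds:
    """Closed byte-scale intervals per HSB channel; a pixel is plant iff all
    three channels fall inside."""

    hue_lo: int = 45
    hue_hi: int = 120
    sat_lo: int = 0
    sat_hi: int = 255
    bri_lo: int = 0
    bri_hi: int = 255

    def __post_init__(self) -> None:
        for lo, hi, name in [
            (self.hue_lo, self.hue_hi, "hue"),
            (self.sat_lo, self.sat_hi, "sat"),
            (self.bri_lo, self.bri_hi, "bri"),
        ]:
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} thresholds must satisfy 0 <= lo <= hi <= 255")


@dataclass
class GreenPixelResult:
    green_count: int
    total_count: int
    green_pct: float
    mask: np.ndarray  # bool, True = plant

    def __post_init__(self) -> None:
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")


def rgb_to_hsb(image: np.ndarray) -> np.ndarray:
    """Convert an RGB byte image to HSB with all channels on the 0–255 scale.

    Standard hexcone transform: hue is rescaled from [0°, 360°) to [0, 255],
    saturation and brightness likewise to [0, 255].  Achromatic pixels
    (max = min) get hue 0 and saturation 0, so gray/black/white can never
    fall in a green hue band.
    """
    image = np.asarray(image)
    if image.ndim < 1 or image.shape[-1] != 3:
        raise ValueError("expected an array with a trailing RGB axis of size 3")
    if image.dtype != np.uint8:
        if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
            image = image.astype(np.uint8)
        else:
            raise ValueError("expected a byte (uint8) RGB image")

    # Photographs have far fewer distinct colors than pixels: convert the
    # unique colors once and scatter the result back.
    if image.ndim >= 2 and image.size >= 3 * 4096:
        flat = image.reshape(-1, 3).astype(np.uint32)
        packed = (flat[:, 0] << 16) | (flat[:, 1] << 8) | flat[:, 2]
        uniq, inverse = np.unique(packed, return_inverse=True)
        if uniq.size < packed.size // 4:
            cols = np.stack(
                [(uniq >> 16) & 255, (uniq >> 8) & 255, uniq & 255], axis=-1
            ).astype(np.uint8)
            return _hsb_core(cols)[inverse].reshape(image.shape)
    return _hsb_core(image)


def _hsb_core(image: np.ndarray) -> np.ndarray:
    # Mirror the classic hexcone formulation on [0, 1] floats so results are
    # bit-identical to the textbook per-pixel form.
    arr = image.astype(np.float64) / 255.0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    maxc = np.max(arr, axis=-1)
    minc = np.min(arr, axis=-1)
    delta = maxc - minc
    chromatic = delta > 0

    s = np.zeros_like(maxc)
    np.divide(delta, maxc, out=s, where=maxc > 0)

    safe_delta = np.where(chromatic, delta, 1.0)
    rc = (maxc - r) / safe_delta
    gc = (maxc - g) / safe_delta
    bc = (maxc - b) / safe_delta
    h = np.where(
        r == maxc, bc - gc, np.where(g == maxc, 2.0 + rc - bc, 4.0 + gc - rc)
    )
    h = (h / 6.0) % 1.0
    h = np.where(chromatic, h, 0.0)

    out = np.empty(image.shape, dtype=np.uint8)
    out[..., 0] = np.rint(h * 255.0)
    out[..., 1] = np.rint(s * 255.0)
    out[..., 2] = np.rint(maxc * 255.0)
    return out


def segment_green(
    image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()
) -> GreenPixelResult:
    """Classify pixels as plant by the HSB thresholds and compute green %."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("zero-size image")
    hsb = rgb_to_hsb(image)
    t = thresholds
    mask = (
        (hsb[..., 0] >= t.hue_lo) & (hsb[..., 0] <= t.hue_hi)
        & (hsb[..., 1] >= t.sat_lo) & (hsb[..., 1] <= t.sat_hi)
        & (hsb[..., 2] >= t.bri_lo) & (hsb[..., 2] <= t.bri_hi)
    )
    green = int(mask.sum())
    total = int(mask.size)
    return GreenPixelResult(green, total, green / total * 100.0, mask)


def green_fraction(
    image: np.ndarray, thresholds: HSBThresholds = HSBThresholds()
) -> float:
    """Green-pixel percentage of one image (convenience wrapper)."""
    return segment_green(image, thresholds).green_pct


def _parse_stem(stem: str) -> tuple[str, str]:
    if "_" not in stem:
        raise ValueError(f"filename {stem!r} not parseable as <plot_id>_<date_id>")
    plot_id, date_id = stem.rsplit("_", 1)
    return plot_id, date_id


def batch_green_fraction(
    image_paths: Sequence[str | Path],
    thresholds: HSBThresholds = HSBThresholds(),
    crop: tuple[int, int, int, int] | None = None,
) -> tuple[pd.DataFrame, list[dict[str, str]]]:
    """Green fraction for a batch of image files.

    Filenames must follow ``<plot_id>_<date_id>.<ext>``.  Returns a table
    (plot_id, date_id, green_pct, green_count, total_count) plus a list of
    per-file error records for unreadable or unparseable files; failures are
    logged, never silently dropped.  ``crop`` is an optional (left, upper,
    right, lower) pixel box applied before segmentation, standing in for the
    physical reference frame cut out of field photographs.
    """
    rows = []
    errors: list[dict[str, str]] = []
    for p in image_paths:
        p = Path(p)
        try:
            plot_id, date_id = _parse_stem(p.stem)
            with Image.open(p) as im:
                im = im.convert("RGB")
                if crop is not None:
                    im = im.crop(crop)
                arr = np.asarray(im)
            res = segment_green(arr, thresholds)
        except Exception as exc:  # noqa: BLE001 - contract: report, don't drop
            logger.warning("skipping %s: %s", p, exc)
            errors.append({"path": str(p), "error": str(exc)})
            continue
        rows.append(
            {
                "plot_id": plot_id,
                "date_id": date_id,
                "green_pct": res.green_pct,
                "green_count": res.green_count,
                "total_count": res.total_count,
            }
        )
    table = pd.DataFrame(
        rows, columns=["plot_id", "date_id", "green_pct", "green_count", "total_count"]
    )
    return table, errors
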