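"""Annotated overlay rendering: ROI contours + RP indexes on the polarity image.

Rendering is pure pixel math (plus PIL's built-in bitmap font for the
numeric labels), so overlays are deterministic and testable by pixel diff.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from skimage.segmentation import find_boundaries

from .dataset import FieldPair
from .profiling import RPResult
from .segmentation import AcinusROI

__all__ = ["render_overlay", "write_annotated_overlay"]

RETAINED_COLOR = (80, 220, 80)
EXCLUDED_COLOR = (230, 70, 70)
TEXT_COLOR = (255, 235, 90)


def _to_gray8(pixels: np.ndarray) -> np.ndarray:
    data = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros(data.shape, dtype=np.uint8)
    return ((data - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def render_overlay(
    pair: FieldPair, rois: list[AcinusROI], results: list[RPResult]
) -> np.ndarray:
    """Render the polarity channel with contours and RP-index labels.

    Retained acini get a green contour and their signed RP index printed
    near the centroid; excluded acini get a red contour and no number.
    With no ROIs the output is just the grayscale polarity image in RGB.
    """
    gray = _to_gray8(pair.polarity.pixels)
    rgb = np.stack([gray, gray, gray], axis=-1)
    by_id = {res.acinus_id: res for res in results}
    shape = pair.polarity.shape
    for roi in rois:
        boundary = find_boundaries(roi.mask(shape), mode="inner")
        rgb[boundary] = RETAINED_COLOR if roi.retained else EXCLUDED_COLOR
    image = Image.fromarray(rgb)
    draw = ImageDraw.Draw(image)
    for roi in rois:
        res = by_id.get(roi.acinus_id)
        if res is None or not roi.retained:
            continue
        r, c = roi.centroid
        draw.text((c - 8, r - 5), f"{res.rp_index:+.2f}", fill=TEXT_COLOR)
    return np.asarray(image)


def write_annotated_overlay(
    pair: FieldPair, rois: list[AcinusROI], results: list[RPResult], out_path: str | Path
) -> None:
    """Write the rendered overlay as PNG."""
    Image.fromarray(render_overlay(pair, rois, results)).save(Path(out_path))
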