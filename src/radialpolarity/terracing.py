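"""Concentric distance-map terracing of acinus ROIs.

Each ROI is read as a topographic mountain: the Euclidean distance of every
ROI pixel to the nearest background pixel is its height, lowest at the edge
and peaking at the center.  Cutting the height range into ``n`` equal bands
yields concentric terraces; terrace 1 is the innermost (radial position 0)
and terrace ``n`` the outermost (radial position 1).  A fixed terrace count
makes profiles comparable across acini of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segmentation import AcinusROI

__all__ = ["TerraceMap", "DegenerateROIError", "terrace_map", "radial_positions"]


class DegenerateROIError(ValueError):
    """ROI too thin or too small to terrace (e.g. 1-px lines)."""


@dataclass
class TerraceMap:
    """Per-pixel terrace assignment for one ROI.

    ``terrace_of_pixel`` is parallel to the ROI's ``rows``/``cols`` arrays
    and holds indices in 1..n (1 = center, n = periphery).
    """

    acinus_id: int
    n_terraces: int
    terrace_of_pixel: np.ndarray
    pixel_counts: np.ndarray  # length n, terrace i at index i-1
    d_max: float

    def __post_init__(self) -> None:
        if self.n_terraces < 2:
            raise ValueError("need at least 2 terraces")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if (self.pixel_counts <= 0).any():
            raise ValueError("every terrace must be nonempty")


def terrace_map(roi: AcinusROI, n: int) -> TerraceMap:
    """Divide a ROI into ``n`` equal-height terraces of its distance map.

    For each ROI pixel, ``d`` is the Euclidean distance to the nearest
    non-ROI pixel (a boundary pixel adjacent to background has d = 1).
    The height bin is ``ceil(n * d / d_max)`` clamped to 1..n, and the
    terrace index counts from the center: ``i = n - bin + 1``.  ROIs whose
    distance map never exceeds 1 px, or that leave any terrace empty,
    are degenerate and raise :class:`DegenerateROIError`.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if roi.area_px < n:
        raise DegenerateROIError(
            f"acinus {roi.acinus_id}: area {roi.area_px} < {n} terraces"
        )
    r0, c0, r1, c1 = roi.bbox
    # pad by 1 so bbox-edge ROI pixels see background
    mask = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    mask[roi.rows - r0 + 1, roi.cols - c0 + 1] = True
    dist = ndi.distance_transform_edt(mask)
    d = dist[roi.rows - r0 + 1, roi.cols - c0 + 1]
    d_max = float(d.max())
    if d_max <= 1.0:
        raise DegenerateROIError(
            f"acinus {roi.acinus_id}: 1-px-thin shape (peak distance {d_max})"
        )
    height_bin = np.ceil(n * d / d_max).astype(np.intp)
    np.clip(height_bin, 1, n, out=height_bin)
    terrace = n - height_bin + 1
    counts = np.bincount(terrace, minlength=n + 1)[1:]
    if (counts == 0).any():
        empty = [i + 1 for i in np.flatnonzero(counts == 0)]
        raise DegenerateROIError(
            f"acinus {roi.acinus_id}: empty terrace(s) {empty} at n={n}"
        )
    return TerraceMap(
        acinus_id=roi.acinus_id,
        n_terraces=n,
        terrace_of_pixel=terrace,
        pixel_counts=counts,
        d_max=d_max,
    )


def radial_positions(tmap: TerraceMap) -> np.ndarray:
    """Normalized mid-band radius of each terrace: r_i = (i - 0.5) / n.

    The acinus center has radial coordinate 0 and the periphery 1, so the
    positions are size-invariant and strictly increasing in the terrace
    index.
    """
    n = tmap.n_terraces
    return (np.arange(1, n + 1) - 0.5) / n
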