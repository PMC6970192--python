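"""Acinus segmentation from the nuclear-stain channel.

The segmentation chain is: 3x3 mean smoothing -> global Otsu threshold ->
morphological border smoothing (opening + closing with a disk) -> optional
hole filling -> watershed on the Euclidean distance transform to split
touching acini -> label dilation to recover the true membrane edge, which
lies outside the nuclear-stain footprint.

Conventions: 0-based (row, col) coordinates, half-open bounding boxes,
8-connectivity for components, labels and watershed divides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

from .raster import ImageRaster

__all__ = [
    "AcinusROI",
    "smooth_mean3x3",
    "otsu_binarize",
    "smooth_mask_borders",
    "fill_mask_holes",
    "watershed_split",
    "dilate_labels",
    "extract_rois",
    "segment_field",
]


@dataclass
class AcinusROI:
    """One segmented acinus: its pixel set plus bookkeeping for filtering.

    ``rows``/``cols`` are parallel coordinate arrays (the pixel set);
    ``excluded_reason`` is ``None`` for retained acini, else one of
    ``"border"``, ``"size"``, ``"blur"``, ``"degenerate"``.
    """

    acinus_id: int
    rows: np.ndarray
    cols: np.ndarray
    area_px: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    touches_border: bool
    wavr: float | None = None
    excluded_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean ROI mask on a grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def smooth_mean3x3(image: ImageRaster) -> ImageRaster:
    """Replace each pixel with the mean of its 3x3 neighborhood.

    Borders use reflected padding; output shape is unchanged.  This is the
    noise-reduction step preceding Otsu thresholding.
    """
    h, w = image.shape
    if h < 3 or w < 3:
        raise ValueError("image must be at least 3x3 for 3x3 mean smoothing")
    out = ndi.uniform_filter(image.as_float(), size=3, mode="reflect")
    np.clip(out, 0.0, None, out=out)  # guard against FP round-off below zero
    return ImageRaster(out, bit_depth="float", pixel_size_um=image.pixel_size_um)


def otsu_binarize(image: ImageRaster) -> np.ndarray:
    """Global Otsu binarization over a 256-bin histogram.

    Returns a boolean mask, true where intensity exceeds the threshold that
    maximizes between-class variance.  A constant image has no threshold:
    an all-false mask is returned with a warning.
    """
    data = image.as_float()
    if np.ptp(data) == 0:
        warnings.warn("constant image: Otsu threshold undefined, empty mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    threshold = filters.threshold_otsu(data, nbins=256)
    return data > threshold


def smooth_mask_borders(mask: np.ndarray, radius: int) -> np.ndarray:
    """Smooth ROI borders by morphological opening then closing (disk).

    ``radius`` 0 is the identity.  Removes single-pixel spurs and notches
    that would otherwise spawn spurious watershed seeds.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    selem = morphology.disk(radius)
    out = morphology.opening(np.asarray(mask, dtype=bool), selem)
    return morphology.closing(out, selem)


def fill_mask_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes of the binary mask.

    The nuclear stain of an acinus is a ring of nuclei around the lumen, so
    the thresholded footprint can be annular; the ROI must cover the whole
    structure for the distance-map terracing to read center-to-periphery.
    """
    return ndi.binary_fill_holes(mask)


def watershed_split(mask: np.ndarray, min_seed_depth: float = 2.0) -> np.ndarray:
    """Split touching acini by watershed on the internal distance map.

    The Euclidean distance to background is computed inside the mask; seeds
    are its regional maxima after h-maxima suppression of depth
    ``min_seed_depth`` (suppression avoids over-segmentation from shallow
    local peaks).  The watershed of the negated distance map partitions the
    mask; pixels on divide lines are set to background.  Returns an int
    label image with labels 1..n (8-connected), 0 for background/divides.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    if min_seed_depth > 0:
        seed_mask = morphology.h_maxima(dist, min_seed_depth)
    else:
        seed_mask = morphology.local_maxima(dist, connectivity=2)
    seed_mask &= mask
    if not seed_mask.any():  # shallow blob: keep it whole
        seed_mask = dist == dist.max()
    markers, _ = ndi.label(seed_mask, structure=np.ones((3, 3), dtype=int))
    labels = segmentation.watershed(
        -dist, markers=markers, mask=mask, connectivity=2, watershed_line=True
    )
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def dilate_labels(labeled: np.ndarray, radius: int) -> np.ndarray:
    """Grow every label by a Euclidean disk of ``radius`` into background.

    A contested pixel (within reach of several labels) goes to the label
    whose original ROI is nearest; exact ties go to the lower label id.
    Labels never merge and every original pixel keeps its label.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labeled = np.asarray(labeled)
    out = labeled.copy()
    if radius == 0:
        return out
    n_labels = int(labeled.max())
    background = labeled == 0
    best = np.full(labeled.shape, np.inf)
    # increasing-id sweep with strict improvement => ties resolve to lower id
    for lab in range(1, n_labels + 1):
        dist = ndi.distance_transform_edt(labeled != lab)
        grow = background & (dist <= radius) & (dist < best)
        out[grow] = lab
        best[grow] = dist[grow]
    return out


def extract_rois(labeled: np.ndarray) -> list[AcinusROI]:
    """Build :class:`AcinusROI` records from a label image.

    Ids are assigned 1..n in raster-scan order of each label's first pixel.
    """
    labeled = np.asarray(labeled)
    h, w = labeled.shape
    props = measure.regionprops(labeled)
    # raster-scan order of the first (topmost, then leftmost) pixel
    def first_pixel_key(p):
        coords = p.coords
        i = np.lexsort((coords[:, 1], coords[:, 0]))[0]
        return (int(coords[i, 0]), int(coords[i, 1]))

    rois: list[AcinusROI] = []
    for new_id, p in enumerate(sorted(props, key=first_pixel_key), start=1):
        rows = p.coords[:, 0].astype(np.intp)
        cols = p.coords[:, 1].astype(np.intp)
        touches = bool(
            (rows == 0).any() or (rows == h - 1).any() or (cols == 0).any() or (cols == w - 1).any()
        )
        r0, c0, r1, c1 = p.bbox
        rois.append(
            AcinusROI(
                acinus_id=new_id,
                rows=rows,
                cols=cols,
                area_px=int(p.area),
                bbox=(r0, c0, r1, c1),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                touches_border=touches,
            )
        )
    return rois


def segment_field(
    nuclear: ImageRaster,
    *,
    border_smooth_radius: int = 2,
    fill_holes: bool = True,
    min_seed_depth: float = 2.0,
    dilation_radius: int = 3,
) -> list[AcinusROI]:
    """Full segmentation chain for one field's nuclear channel."""
    nuclear.check_analyzable()
    smoothed = smooth_mean3x3(nuclear)
    mask = otsu_binarize(smoothed)
    mask = smooth_mask_borders(mask, border_smooth_radius)
    if fill_holes:
        mask = fill_mask_holes(mask)
    labels = watershed_split(mask, min_seed_depth=min_seed_depth)
    labels = dilate_labels(labels, dilation_radius)
    return extract_rois(labels)
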