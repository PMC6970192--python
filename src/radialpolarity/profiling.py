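"""Radial intensity profiles and the signed radial-polarity (RP) index.

For each retained acinus, the mean polarity-marker intensity of every
terrace is divided by the mean intensity over the whole ROI, giving a
normalized profile RP_1..RP_n that is independent of staining efficacy
(multiplying the image by any c > 0 leaves it unchanged).  The profile is
collapsed into a single index,

    RP = sum_i |1 - RP_i|,

a dispersion of the profile about the flat line RP = 1: the larger the
index, the more radially concentrated the marker.  The sign encodes the
direction of polarity: descending profiles (marker concentrated toward the
center, apical) are positive, ascending profiles (peripheral, basal) are
negative, judged by the least-squares slope of RP_i against the normalized
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FieldPair
from .raster import ImageRaster
from .segmentation import AcinusROI
from .terracing import TerraceMap, radial_positions

__all__ = [
    "RadialProfile",
    "RPResult",
    "UnstainableROIError",
    "radial_profile",
    "polarity_sign",
    "rp_index",
    "profile_acinus",
]

#: slope magnitudes below this are treated as flat (sign 0)
SLOPE_EPSILON = 1e-9


class UnstainableROIError(ValueError):
    """ROI with zero mean polarity intensity; profile undefined."""


@dataclass
class RadialProfile:
    """Normalized per-terrace intensities of one acinus."""

    acinus_id: int
    n: int
    rp: np.ndarray  # RP_1..RP_n, dimensionless
    pixel_counts: np.ndarray
    mean_total: float  # whole-ROI mean intensity (the normalizer)

    def __post_init__(self) -> None:
        if self.mean_total <= 0:
            raise ValueError("mean_total must be positive")
        if (self.rp < 0).any():
            raise ValueError("RP_i must be non-negative")


@dataclass
class RPResult:
    """Signed polarity summary of one acinus, with provenance."""

    acinus_id: int
    condition: str
    field_id: str
    profile: RadialProfile
    rp_index: float
    sign: int  # +1 apical, -1 basal, 0 flat
    slope: float


def radial_profile(polarity: ImageRaster, roi: AcinusROI, tmap: TerraceMap) -> RadialProfile:
    """Normalized radial intensity profile of the polarity channel.

    RP_i = (mean intensity over terrace-i pixels) / (mean over all ROI
    pixels).  Raises :class:`UnstainableROIError` when the whole-ROI mean
    is zero (no signal to normalize by).
    """
    data = polarity.as_float()
    values = data[roi.rows, roi.cols]
    mean_total = float(values.mean())
    if mean_total <= 0:
        raise UnstainableROIError(f"acinus {roi.acinus_id}: zero mean polarity intensity")
    n = tmap.n_terraces
    sums = np.bincount(tmap.terrace_of_pixel, weights=values, minlength=n + 1)[1:]
    rp = (sums / tmap.pixel_counts) / mean_total
    return RadialProfile(
        acinus_id=roi.acinus_id,
        n=n,
        rp=rp,
        pixel_counts=tmap.pixel_counts.copy(),
        mean_total=mean_total,
    )


def polarity_sign(profile: RadialProfile, radii: np.ndarray) -> tuple[int, float]:
    """Direction of polarity from the profile's least-squares slope.

    Returns ``(sign, slope)`` where slope is the OLS slope of RP_i against
    the normalized radius r_i.  Descending (negative slope) means the
    marker peaks centrally => apical => sign +1; ascending => basal =>
    sign -1; |slope| below a small epsilon => 0 (flat profile).
    """
    if profile.n < 2:
        raise ValueError("need at least 2 terraces to estimate a slope")
    r = np.asarray(radii, dtype=np.float64)
    y = profile.rp
    r_c = r - r.mean()
    slope = float((r_c * (y - y.mean())).sum() / (r_c**2).sum())
    if slope < -SLOPE_EPSILON:
        return 1, slope
    if slope > SLOPE_EPSILON:
        return -1, slope
    return 0, slope


def rp_index(profile: RadialProfile, sign: int) -> float:
    """Signed radial-polarity index: sign * sum_i |1 - RP_i|."""
    magnitude = float(np.abs(1.0 - profile.rp).sum())
    return sign * magnitude


def profile_acinus(
    polarity: ImageRaster,
    roi: AcinusROI,
    tmap: TerraceMap,
    condition: str = "",
    field_id: str = "",
) -> RPResult:
    """Profile one acinus end to end: profile, sign, signed index."""
    profile = radial_profile(polarity, roi, tmap)
    sign, slope = polarity_sign(profile, radial_positions(tmap))
    return RPResult(
        acinus_id=roi.acinus_id,
        condition=condition,
        field_id=field_id,
        profile=profile,
        rp_index=rp_index(profile, sign),
        sign=sign,
        slope=slope,
    )
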