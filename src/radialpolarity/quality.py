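"""Quality filtering: border/size exclusion and the WAVR focus measure.

Out-of-focus acini bias radial profiles toward flatness, so a focus metric
is computed per acinus on the nuclear channel and structures below a cutoff
are excluded.  The metric is the wavelet energy ratio WAVR: the ratio of
detail-subband to approximation-subband energy of a single-level Daubechies-6
transform.  Defocus removes high-frequency content, so WAVR decreases
monotonically with blur.  Because the absolute WAVR scale depends on the
imaging system and crop statistics, a data-driven cutoff (per-class normal
fits + equal-density intersection) is provided alongside a fixed cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.optimize import curve_fit

from .raster import ImageRaster
from .segmentation import AcinusROI

__all__ = [
    "NormalFit",
    "FitError",
    "wavr_focus",
    "apply_filters",
    "wavr_histogram",
    "fit_normal",
    "choose_cutoff",
    "auto_cutoff",
]

MIN_CROP_SIDE = 16


@dataclass
class NormalFit:
    """Parameters of an amplitude-scaled normal density fitted to a histogram."""

    mean: float
    sd: float
    amplitude: float
    rss: float

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.amplitude <= 0:
            raise ValueError("sd and amplitude must be strictly positive")

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude * np.exp(-((x - self.mean) ** 2) / (2.0 * self.sd**2))


class FitError(RuntimeError):
    """Non-convergent normal fit; carries the last iterate."""

    def __init__(self, message: str, last_iterate: tuple[float, float, float] | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


def _pad_to_min(crop: np.ndarray, min_side: int = MIN_CROP_SIDE) -> np.ndarray:
    pad_r = max(0, min_side - crop.shape[0])
    pad_c = max(0, min_side - crop.shape[1])
    if pad_r or pad_c:
        crop = np.pad(
            crop,
            ((0, pad_r), (0, pad_c)),
            mode="reflect" if min(crop.shape) > 1 else "edge",
        )
    return crop


def wavr_focus(image_crop: ImageRaster | np.ndarray) -> float:
    """Wavelet energy-ratio focus measure of an image crop.

    The crop is rescaled to [0, 1] (making the measure invariant to
    multiplicative intensity scaling and offsets), transformed with a
    single-level 2-D db6 DWT, and each subband is reconstructed to image
    space.  WAVR = (sum |H|^2 + sum |V|^2 + sum |D|^2) / sum |A|^2.  Higher
    means sharper; a constant crop has no detail energy and returns 0.
    """
    crop = image_crop.as_float() if isinstance(image_crop, ImageRaster) else np.asarray(
        image_crop, dtype=np.float64
    )
    crop = _pad_to_min(crop)
    lo, hi = float(crop.min()), float(crop.max())
    if hi == lo:
        warnings.warn("constant crop: WAVR undefined, returning 0", stacklevel=2)
        return 0.0
    crop = (crop - lo) / (hi - lo)
    cA, (cH, cV, cD) = pywt.dwt2(crop, "db6")
    zeros = np.zeros_like(cA)
    approx = pywt.idwt2((cA, (zeros, zeros, zeros)), "db6")
    detail_energy = 0.0
    for band in (cH, cV, cD):
        rec = pywt.idwt2((zeros, tuple(band if b is band else zeros for b in (cH, cV, cD))), "db6")
        detail_energy += float(np.sum(rec**2))
    approx_energy = float(np.sum(approx**2))
    if approx_energy == 0.0:
        return 0.0
    return detail_energy / approx_energy


def _bbox_crop(image: ImageRaster, roi: AcinusROI) -> np.ndarray:
    r0, c0, r1, c1 = roi.bbox
    return image.as_float()[r0:r1, c0:c1]


def apply_filters(
    rois: list[AcinusROI],
    nuclear: ImageRaster,
    min_area: int,
    max_area: int,
    cutoff: float,
) -> list[AcinusROI]:
    """Apply exclusion rules in order border -> size -> blur, in place.

    The first failing rule is recorded as ``excluded_reason``.  WAVR is
    computed (on the un-masked nuclear bbox crop) only for ROIs that survive
    the border and size rules; retained ROIs end with ``excluded_reason``
    None.  Idempotent: re-application does not change decisions.
    """
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    for roi in rois:
        roi.excluded_reason = None
        roi.wavr = None
        if roi.touches_border:
            roi.excluded_reason = "border"
            continue
        if not (min_area <= roi.area_px <= max_area):
            roi.excluded_reason = "size"
            continue
        roi.wavr = wavr_focus(_bbox_crop(nuclear, roi))
        if roi.wavr < cutoff:
            roi.excluded_reason = "blur"
    return rois


def wavr_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram WAVR values with the Freedman-Diaconis rule.

    Returns (bin_centers, counts).
    """
    values = np.asarray(values, dtype=np.float64)
    counts, edges = np.histogram(values, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _gauss(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


def fit_normal(
    bin_centers: np.ndarray, counts: np.ndarray, max_iterations: int = 2000
) -> NormalFit:
    """Levenberg-Marquardt fit of an amplitude-scaled normal to bin heights.

    Initialized from the histogram's weighted mean and standard deviation.
    Requires at least 5 nonzero bins; raises :class:`FitError` on
    non-convergence (carrying the last iterate).
    """
    x = np.asarray(bin_centers, dtype=np.float64)
    y = np.asarray(counts, dtype=np.float64)
    if np.count_nonzero(y) < 5:
        raise ValueError("need at least 5 nonzero bins to fit a normal")
    total = y.sum()
    mean0 = float((x * y).sum() / total)
    sd0 = float(math.sqrt(max(((x - mean0) ** 2 * y).sum() / total, 1e-12)))
    amp0 = float(y.max())
    p0 = (amp0, mean0, sd0)
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, method="lm", maxfev=max_iterations)
    except RuntimeError as exc:
        raise FitError(f"normal fit did not converge: {exc}", last_iterate=p0) from exc
    amplitude, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    rss = float(np.sum((y - _gauss(x, amplitude, mean, sd)) ** 2))
    return NormalFit(mean=mean, sd=sd, amplitude=abs(amplitude), rss=rss)


def choose_cutoff(fit_blurry: NormalFit, fit_sharp: NormalFit) -> float:
    """Equal-likelihood boundary between the blurry and sharp WAVR classes.

    Returns the intersection of the two fitted normal densities that lies
    between the class means; if no intersection falls there, falls back to
    the midpoint of the means.  Requires ``fit_blurry.mean < fit_sharp.mean``.
    """
    m1, s1, a1 = fit_blurry.mean, fit_blurry.sd, fit_blurry.amplitude
    m2, s2, a2 = fit_sharp.mean, fit_sharp.sd, fit_sharp.amplitude
    if m1 == m2:
        raise ValueError("class means are equal: classes inseparable")
    if m1 > m2:
        raise ValueError("fit_blurry.mean must be below fit_sharp.mean")
    midpoint = 0.5 * (m1 + m2)
    # a1 exp(-(x-m1)^2/2s1^2) = a2 exp(-(x-m2)^2/2s2^2), quadratic in x
    qa = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    qb = m1 / s1**2 - m2 / s2**2
    qc = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log(a1 / a2)
    if abs(qa) < 1e-300:  # equal spreads: linear equation
        if qb == 0:
            return midpoint
        roots = [-qc / qb]
    else:
        disc = qb**2 - 4 * qa * qc
        if disc < 0:
            return midpoint
        sq = math.sqrt(disc)
        roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
    between = [r for r in roots if m1 < r < m2]
    if not between:
        return midpoint
    return min(between, key=lambda r: abs(r - midpoint))


def auto_cutoff(values: np.ndarray, seed: int = 0) -> float:
    """Data-driven WAVR cutoff from an unlabeled mixed sample.

    Fits a two-component 1-D Gaussian mixture and returns the equal-density
    intersection of the two components (weight-scaled), so the cutoff adapts
    to the imaging system's WAVR scale without visual class labels.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    if len(values) < 10:
        raise ValueError("need at least 10 WAVR values for automatic cutoff selection")
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(values)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    fits = [
        NormalFit(
            mean=float(means[i]),
            sd=float(max(sds[i], 1e-9)),
            amplitude=float(max(weights[i] / sds[i], 1e-12)),
            rss=0.0,
        )
        for i in order
    ]
    return choose_cutoff(fits[0], fits[1])
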