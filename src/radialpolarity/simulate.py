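"""Synthetic acinus field generator with ground truth.

Emulates two-channel epifluorescence fields of cultured breast acini so
every pipeline stage can be exercised against known truth.  Each acinus is
a disk of radius R; its nuclear channel is a ring of Gaussian nuclei at
radius 0.7 R around the center (a ring because the cells surround a small
lumen — and deliberately under-covering the true extent, which is what the
ROI dilation step compensates for).  The polarity channel follows a linear
radial law in the normalized radius rho = r/R:

    apical:    I(rho) = 1 + a (1 - rho)   (bright center)
    basal:     I(rho) = 1 + a rho         (bright rim)
    nonpolar:  I(rho) = 1                 (flat)

with gradient strength ``a``, scaled to the configured dynamic range.
Fields get additive Gaussian noise, and a configurable fraction of acini is
defocused by Gaussian convolution.  Everything is deterministic given the
seed, and the output is ordinary pipeline input (same rasters, readers and
configuration as real data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .dataset import FieldPair
from .raster import ImageRaster, write_raster

__all__ = [
    "SimulationConfig",
    "AcinusTruth",
    "GroundTruth",
    "PlacementError",
    "simulate_field",
    "blur_series",
    "write_simulated_dataset",
    "evaluate_against_truth",
    "evaluate_tables",
    "ground_truth_from_dataframe",
]

PHENOTYPES = ("apical", "basal", "nonpolar")


class PlacementError(RuntimeError):
    """Could not place the requested acini without overlap."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic field.

    Intensities are in camera counts on a 16-bit-like scale: the signal
    dynamic range is ``dynamic_range`` counts over a ``background`` floor,
    and ``noise_sd`` is the additive Gaussian noise in counts.  The default
    (50 counts, 0.5% of the dynamic range) models the read-noise floor of a
    cooled sCMOS camera at a well-exposed acquisition; signal-dependent
    shot noise is not modeled.
    """

    image_size: tuple[int, int] = (384, 384)
    n_acini: int = 8
    radius_range: tuple[float, float] = (15.0, 28.0)
    phenotype_mix: dict[str, float] = field(
        default_factory=lambda: {"apical": 1 / 3, "basal": 1 / 3, "nonpolar": 1 / 3}
    )
    gradient_strength: float = 1.0
    nuclei_per_acinus: int = 12
    nucleus_radius: float = 2.5
    texture_strength: float = 0.35
    psf_sigma: float = 0.8
    membrane_px: float = 2.0
    noise_sd: float = 50.0
    defocus_fraction: float = 0.0
    defocus_sigma: float = 3.0
    seed: int = 0
    background: float = 200.0
    dynamic_range: float = 10000.0
    min_separation: float = 2.0
    touching_pairs: int = 0
    placements: list[tuple[float, float, float, str]] | None = None  # (row, col, R, phenotype)

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("phenotype_mix proportions must sum to 1")
        if any(k not in PHENOTYPES for k in self.phenotype_mix):
            raise ValueError(f"phenotypes must be among {PHENOTYPES}")
        if self.radius_range[0] < 5:
            raise ValueError("acinus radii below 5 px are not resolvable")
        if self.gradient_strength < 0 or self.noise_sd < 0:
            raise ValueError("gradient_strength and noise_sd must be >= 0")


@dataclass
class AcinusTruth:
    """Simulator record of one synthetic acinus."""

    center: tuple[float, float]  # (row, col)
    radius: float
    phenotype: str
    defocused: bool
    touches_border: bool


@dataclass
class GroundTruth:
    """All truth records for one simulated field."""

    condition: str
    field_id: str
    records: list[AcinusTruth]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": self.condition,
                    "field_id": self.field_id,
                    "row": rec.center[0],
                    "col": rec.center[1],
                    "radius": rec.radius,
                    "phenotype": rec.phenotype,
                    "defocused": rec.defocused,
                    "touches_border": rec.touches_border,
                }
                for rec in self.records
            ]
        )


def _sample_placements(config: SimulationConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk placements (plus touching pairs)."""
    h, w = config.image_size
    placed: list[tuple[float, float, float]] = []
    lo, hi = config.radius_range
    n_single = config.n_acini - 2 * config.touching_pairs
    if n_single < 0:
        raise ValueError("touching_pairs exceed n_acini")

    def fits(r: float, c: float, radius: float) -> bool:
        for pr, pc, prad in placed:
            if math.hypot(r - pr, c - pc) < radius + prad + config.min_separation:
                return False
        return True

    tries = 0
    for _ in range(config.touching_pairs):
        while True:
            tries += 1
            if tries > 10000:
                raise PlacementError("placement infeasible; use fewer or smaller acini")
            rad1, rad2 = rng.uniform(lo, hi, size=2)
            r = rng.uniform(rad1 + 2, h - rad1 - 2)
            c = rng.uniform(rad1 + 2, w - rad1 - 2)
            ang = rng.uniform(0, 2 * math.pi)
            d = 0.8 * (rad1 + rad2)  # overlapping: watershed must split them
            r2, c2 = r + d * math.sin(ang), c + d * math.cos(ang)
            if not (rad2 + 2 <= r2 <= h - rad2 - 2 and rad2 + 2 <= c2 <= w - rad2 - 2):
                continue
            if fits(r, c, rad1 + rad2 + d) and fits(r2, c2, 0):
                placed.append((r, c, rad1))
                placed.append((r2, c2, rad2))
                break
    for _ in range(n_single):
        while True:
            tries += 1
            if tries > 10000:
                raise PlacementError("placement infeasible; use fewer or smaller acini")
            radius = rng.uniform(lo, hi)
            r = rng.uniform(radius + 2, h - radius - 2)
            c = rng.uniform(radius + 2, w - radius - 2)
            if fits(r, c, radius):
                placed.append((r, c, radius))
                break
    return placed


def _radial_law(rho: np.ndarray, phenotype: str, a: float) -> np.ndarray:
    if phenotype == "apical":
        return 1.0 + a * (1.0 - rho)
    if phenotype == "basal":
        return 1.0 + a * rho
    return np.ones_like(rho)


def simulate_field(
    config: SimulationConfig, condition: str = "sim", field_id: str = "field_000"
) -> tuple[FieldPair, GroundTruth]:
    """Render one synthetic field pair plus its ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    images and records.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    if config.placements is not None:
        placements = [(r, c, rad) for r, c, rad, _ in config.placements]
        phenotypes = [p for _, _, _, p in config.placements]
    else:
        placements = _sample_placements(config, rng)
        names = list(config.phenotype_mix)
        probs = np.array([config.phenotype_mix[k] for k in names])
        phenotypes = [names[i] for i in rng.choice(len(names), size=len(placements), p=probs)]
    n = len(placements)
    defocused = rng.random(n) < config.defocus_fraction

    nuclear = np.zeros((h, w), dtype=np.float64)
    polarity = np.zeros((h, w), dtype=np.float64)
    records: list[AcinusTruth] = []
    nuc_amp = 0.8 * config.dynamic_range
    pol_base = config.dynamic_range / 3.0

    for (cr, cc, radius), phen, blur in zip(placements, phenotypes, defocused):
        margin = int(math.ceil(radius + 3 * config.defocus_sigma + 3 * config.nucleus_radius))
        r0, r1 = max(0, int(cr) - margin), min(h, int(cr) + margin + 1)
        c0, c1 = max(0, int(cc) - margin), min(w, int(cc) + margin + 1)
        rows, cols = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dist = np.hypot(rows - cr, cols - cc)

        # nuclear: contiguous ring of nuclei at 0.7 R — a smooth chromatin band
        # (cells abut each other around the lumen) with per-nucleus bright bumps
        ring = 0.7 * radius
        band_width = max(2.5, 0.45 * config.nucleus_radius + 0.08 * radius)
        nuc_patch = 0.45 * nuc_amp * np.exp(-((dist - ring) ** 2) / (2.0 * band_width**2))
        k = config.nuclei_per_acinus
        angles = np.linspace(0, 2 * math.pi, k, endpoint=False) + rng.uniform(0, 2 * math.pi / k)
        jitter = rng.normal(0.0, 0.06 * radius, size=(k, 2))
        # nuclei are hard-edged disks: in-focus images carry genuine edge
        # detail (as real stains do), which defocus destroys
        for ang, (jr, jc) in zip(angles, jitter):
            nr = cr + ring * math.sin(ang) + jr
            nc = cc + ring * math.cos(ang) + jc
            d2 = (rows - nr) ** 2 + (cols - nc) ** 2
            nuc_patch += 0.55 * nuc_amp * (d2 <= config.nucleus_radius**2)
        # chromatin texture: signal-proportional speckle, also erased by defocus
        speckle = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=nuc_patch.shape), 1.0)
        nuc_patch *= np.clip(1.0 + config.texture_strength * speckle, 0.0, None)
        nuc_patch = ndi.gaussian_filter(nuc_patch, config.psf_sigma)

        # polarity: linear radial law inside the disk; the boundary value
        # extends membrane_px outward (markers sit in a shell of finite
        # thickness, so the dilated ROI does not fall off a hard edge)
        inside = dist <= radius + config.membrane_px
        rho = np.clip(dist / radius, 0.0, 1.0)
        pol_patch = np.where(inside, pol_base * _radial_law(rho, phen, config.gradient_strength), 0.0)
        pol_patch = ndi.gaussian_filter(pol_patch, config.psf_sigma)

        if blur:
            nuc_patch = ndi.gaussian_filter(nuc_patch, config.defocus_sigma)
            pol_patch = ndi.gaussian_filter(pol_patch, config.defocus_sigma)
        nuclear[r0:r1, c0:c1] += nuc_patch
        polarity[r0:r1, c0:c1] += pol_patch

        touches = cr - radius <= 0 or cc - radius <= 0 or cr + radius >= h - 1 or cc + radius >= w - 1
        records.append(
            AcinusTruth(
                center=(cr, cc), radius=radius, phenotype=phen, defocused=bool(blur), touches_border=touches
            )
        )

    for img in (nuclear, polarity):
        img += config.background
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        np.clip(img, 0.0, 65535.0, out=img)

    pair = FieldPair(
        condition=condition,
        field_id=field_id,
        nuclear=ImageRaster(np.round(nuclear).astype(np.uint16), bit_depth=16),
        polarity=ImageRaster(np.round(polarity).astype(np.uint16), bit_depth=16),
    )
    return pair, GroundTruth(condition=condition, field_id=field_id, records=records)


def blur_series(image: ImageRaster, sigmas: list[float]) -> list[ImageRaster]:
    """Gaussian-blur degradation series (sigma 0 = identity)."""
    if any(s < 0 for s in sigmas) or list(sigmas) != sorted(sigmas):
        raise ValueError("sigmas must be non-negative and increasing")
    out = []
    data = image.as_float()
    for sigma in sigmas:
        blurred = data.copy() if sigma == 0 else ndi.gaussian_filter(data, sigma)
        out.append(ImageRaster(np.clip(blurred, 0, None), bit_depth="float", pixel_size_um=image.pixel_size_um))
    return out


def write_simulated_dataset(
    root: str | Path,
    conditions: dict[str, SimulationConfig],
    n_fields: int = 3,
    nuclear_suffix: str = "_dapi",
    polarity_suffix: str = "_pol",
) -> pd.DataFrame:
    """Write a pipeline-readable dataset (per-condition TIFF folders) + truth CSV.

    Each field derives its seed from the condition config's seed, so the
    whole dataset is reproducible from the configs alone.  Returns the
    concatenated ground-truth table (also written to ``ground_truth.csv``).
    """
    root = Path(root)
    truth_frames = []
    for cond in sorted(conditions):
        cfg = conditions[cond]
        cond_dir = root / cond
        cond_dir.mkdir(parents=True, exist_ok=True)
        for i in range(n_fields):
            fid = f"field_{i:03d}"
            pair, truth = simulate_field(
                replace(cfg, seed=cfg.seed + i), condition=cond, field_id=fid
            )
            write_raster(pair.nuclear, cond_dir / f"{fid}{nuclear_suffix}.tif")
            write_raster(pair.polarity, cond_dir / f"{fid}{polarity_suffix}.tif")
            truth_frames.append(truth.to_dataframe())
    table = pd.concat(truth_frames, ignore_index=True)
    table.to_csv(root / "ground_truth.csv", index=False)
    return table


def ground_truth_from_dataframe(df: pd.DataFrame) -> list[GroundTruth]:
    """Rebuild per-field :class:`GroundTruth` records from the truth table."""
    truths = []
    for (cond, fid), grp in df.groupby(["condition", "field_id"], sort=True):
        records = [
            AcinusTruth(
                center=(float(r.row), float(r.col)),
                radius=float(r.radius),
                phenotype=str(r.phenotype),
                defocused=bool(r.defocused),
                touches_border=bool(r.touches_border),
            )
            for r in grp.itertuples()
        ]
        truths.append(GroundTruth(condition=str(cond), field_id=str(fid), records=records))
    return truths


def evaluate_tables(
    results: pd.DataFrame, truth: pd.DataFrame, match_radius: float = 10.0
) -> dict:
    """Evaluate a results CSV against a ground-truth CSV.

    Field ids must correspond exactly; mismatches raise with the offending
    ids listed.  Delegates to :func:`evaluate_against_truth` via lightweight
    row adapters, so both entry points score identically.
    """
    from types import SimpleNamespace

    res_fields = set(zip(results["condition"].astype(str), results["field_id"].astype(str)))
    truth_fields = set(zip(truth["condition"].astype(str), truth["field_id"].astype(str)))
    extra = sorted(res_fields - truth_fields)
    if extra:
        raise ValueError(f"results reference fields absent from ground truth: {extra}")

    truths = ground_truth_from_dataframe(truth)
    analyses = []
    for (cond, fid), grp in results.groupby(["condition", "field_id"], sort=True):
        rois, scored = [], []
        for r in grp.itertuples():
            reason = str(r.excluded_reason) if isinstance(r.excluded_reason, str) and r.excluded_reason else None
            wavr = None if pd.isna(r.wavr) else float(r.wavr)
            rois.append(
                SimpleNamespace(
                    acinus_id=int(r.acinus_id),
                    centroid=(float(r.centroid_row), float(r.centroid_col)),
                    wavr=wavr,
                    excluded_reason=reason,
                )
            )
            if reason is None and not pd.isna(r.rp_index):
                scored.append(
                    SimpleNamespace(
                        acinus_id=int(r.acinus_id), rp_index=float(r.rp_index), sign=int(r.sign)
                    )
                )
        analyses.append(
            SimpleNamespace(
                pair=SimpleNamespace(condition=str(cond), field_id=str(fid)),
                rois=rois,
                results=scored,
            )
        )
    # fields present in truth but without any detected ROI still count in the denominator
    for cond, fid in sorted(truth_fields - res_fields):
        analyses.append(
            SimpleNamespace(pair=SimpleNamespace(condition=cond, field_id=fid), rois=[], results=[])
        )
    return evaluate_against_truth(analyses, truths, match_radius=match_radius)


EXPECTED_SIGN = {"apical": 1, "basal": -1}


def evaluate_against_truth(
    analyses: list, truths: list[GroundTruth], match_radius: float = 10.0
) -> dict:
    """Score pipeline output against simulator ground truth.

    Detected ROIs are matched to truth acini by centroid distance (nearest
    within ``match_radius``).  Reports detection sensitivity (of
    non-border truth acini), focus-filter sensitivity/specificity (blur
    exclusion vs. the defocused flag, among matched ROIs with a WAVR
    value), per-phenotype sign-recovery accuracy, and per-phenotype
    RP-index summaries.
    """
    truth_by_field = {(t.condition, t.field_id): t for t in truths}
    matched = []  # (truth record, roi, result or None)
    n_truth_eligible = 0
    n_detected_eligible = 0
    for fa in analyses:
        key = (fa.pair.condition, fa.pair.field_id)
        if key not in truth_by_field:
            raise ValueError(f"no ground truth for field {key}")
        records = truth_by_field[key].records
        n_truth_eligible += sum(1 for rec in records if not rec.touches_border)
        by_id = {res.acinus_id: res for res in fa.results}
        for roi in fa.rois:
            best, best_d = None, match_radius
            for rec in records:
                d = math.hypot(roi.centroid[0] - rec.center[0], roi.centroid[1] - rec.center[1])
                if d <= best_d:
                    best, best_d = rec, d
            if best is not None:
                matched.append((best, roi, by_id.get(roi.acinus_id)))
                if not best.touches_border:
                    n_detected_eligible += 1

    report: dict = {
        "n_truth": sum(len(t.records) for t in truths),
        "n_detected": sum(len(fa.rois) for fa in analyses),
        "detection_sensitivity": (
            min(n_detected_eligible, n_truth_eligible) / n_truth_eligible if n_truth_eligible else float("nan")
        ),
    }

    with_wavr = [(rec, roi) for rec, roi, _ in matched if roi.wavr is not None]
    defocused = [(rec, roi) for rec, roi in with_wavr if rec.defocused]
    sharp = [(rec, roi) for rec, roi in with_wavr if not rec.defocused]
    report["focus_sensitivity"] = (
        sum(roi.excluded_reason == "blur" for _, roi in defocused) / len(defocused)
        if defocused
        else float("nan")
    )
    report["focus_specificity"] = (
        sum(roi.excluded_reason != "blur" for _, roi in sharp) / len(sharp)
        if sharp
        else float("nan")
    )

    for phen in PHENOTYPES:
        scored = [res for rec, _, res in matched if res is not None and rec.phenotype == phen]
        values = np.array([res.rp_index for res in scored])
        report[f"n_scored_{phen}"] = len(scored)
        report[f"rp_index_mean_{phen}"] = float(values.mean()) if len(scored) else float("nan")
        report[f"rp_index_sd_{phen}"] = float(values.std(ddof=1)) if len(scored) > 1 else float("nan")
        if phen in EXPECTED_SIGN and scored:
            hits = sum(res.sign == EXPECTED_SIGN[phen] for res in scored)
            report[f"sign_accuracy_{phen}"] = hits / len(scored)
    return report
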