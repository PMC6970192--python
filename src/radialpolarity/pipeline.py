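"""Per-field and whole-dataset analysis orchestration.

``analyze_field`` runs segmentation -> filtering -> terracing -> profiling
for one field and is fully deterministic given the configuration.  A
dataset run first segments every field and pools the WAVR values so the
blur cutoff can optionally be chosen from the data, then finalizes each
field and assembles the results table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .dataset import FieldPair
from .profiling import RPResult, UnstainableROIError, profile_acinus
from .quality import apply_filters, auto_cutoff
from .segmentation import AcinusROI, segment_field
from .terracing import DegenerateROIError, terrace_map

__all__ = ["FieldAnalysis", "analyze_field", "analyze_dataset", "results_table"]

logger = logging.getLogger("radialpolarity")


@dataclass
class FieldAnalysis:
    """Everything computed for one field."""

    pair: FieldPair
    rois: list[AcinusROI]
    results: list[RPResult]  # one per retained acinus

    @property
    def counts(self) -> dict[str, int]:
        c = {"detected": len(self.rois), "border": 0, "size": 0, "blur": 0, "degenerate": 0}
        for roi in self.rois:
            if roi.excluded_reason:
                c[roi.excluded_reason] += 1
        c["retained"] = c["detected"] - c["border"] - c["size"] - c["blur"] - c["degenerate"]
        return c


def _segment_and_measure(pair: FieldPair, config: RunConfig) -> list[AcinusROI]:
    """Segmentation plus border/size filtering and WAVR measurement.

    The blur decision is deferred (cutoff 0 excludes nothing) so that a
    dataset-level automatic cutoff can be applied afterwards.
    """
    rois = segment_field(
        pair.nuclear,
        border_smooth_radius=config.border_smooth_radius,
        fill_holes=config.fill_holes,
        min_seed_depth=config.seed_suppression_depth,
        dilation_radius=config.dilation_radius,
    )
    return apply_filters(rois, pair.nuclear, config.min_area, config.max_area, cutoff=0.0)


def _finalize_field(pair: FieldPair, rois: list[AcinusROI], cutoff: float, config: RunConfig) -> FieldAnalysis:
    """Apply the blur cutoff, then terrace and profile the retained acini."""
    for roi in rois:
        if roi.excluded_reason is None and roi.wavr is not None and roi.wavr < cutoff:
            roi.excluded_reason = "blur"
    results: list[RPResult] = []
    for roi in rois:
        if roi.excluded_reason is not None:
            continue
        try:
            tmap = terrace_map(roi, config.n_terraces)
            results.append(
                profile_acinus(pair.polarity, roi, tmap, condition=pair.condition, field_id=pair.field_id)
            )
        except (DegenerateROIError, UnstainableROIError) as exc:
            logger.info("excluding acinus as degenerate: %s", exc)
            roi.excluded_reason = "degenerate"
    return FieldAnalysis(pair=pair, rois=rois, results=results)


def analyze_field(pair: FieldPair, config: RunConfig | None = None) -> FieldAnalysis:
    """Full pipeline for one field with a fixed (numeric) blur cutoff."""
    config = config or RunConfig()
    if config.wavr_cutoff == "auto":
        raise ValueError("automatic cutoff needs a whole dataset; use analyze_dataset")
    rois = _segment_and_measure(pair, config)
    return _finalize_field(pair, rois, float(config.wavr_cutoff), config)


def analyze_dataset(pairs: list[FieldPair], config: RunConfig | None = None) -> tuple[list[FieldAnalysis], float]:
    """Analyze all fields; resolves ``wavr_cutoff='auto'`` from pooled WAVR.

    Returns the per-field analyses and the cutoff actually used.
    """
    config = config or RunConfig()
    measured = [(pair, _segment_and_measure(pair, config)) for pair in pairs]
    if config.wavr_cutoff == "auto":
        wavrs = np.array(
            [roi.wavr for _, rois in measured for roi in rois if roi.wavr is not None]
        )
        cutoff = auto_cutoff(wavrs, seed=config.seed)
        logger.info("automatic WAVR cutoff: %.4g (from %d acini)", cutoff, len(wavrs))
    else:
        cutoff = float(config.wavr_cutoff)
    analyses = [_finalize_field(pair, rois, cutoff, config) for pair, rois in measured]
    for fa in analyses:
        logger.info(
            "field %s/%s counts: %s", fa.pair.condition, fa.pair.field_id, fa.counts
        )
    return analyses, cutoff


def results_table(analyses: list[FieldAnalysis], n_terraces: int) -> pd.DataFrame:
    """One row per detected acinus (excluded ones keep their reason).

    RP columns are populated only for retained acini.
    """
    rp_cols = [f"RP_{i}" for i in range(1, n_terraces + 1)]
    rows = []
    for fa in analyses:
        by_id = {res.acinus_id: res for res in fa.results}
        for roi in fa.rois:
            row: dict[str, object] = {
                "condition": fa.pair.condition,
                "field_id": fa.pair.field_id,
                "acinus_id": roi.acinus_id,
                "area_px": roi.area_px,
                "centroid_row": roi.centroid[0],
                "centroid_col": roi.centroid[1],
                "wavr": np.nan if roi.wavr is None else roi.wavr,
                "excluded_reason": roi.excluded_reason or "",
            }
            res = by_id.get(roi.acinus_id)
            if res is not None:
                for col, value in zip(rp_cols, res.profile.rp):
                    row[col] = value
                row["rp_index"] = res.rp_index
                row["sign"] = res.sign
            else:
                for col in rp_cols:
                    row[col] = np.nan
                row["rp_index"] = np.nan
                row["sign"] = np.nan
            rows.append(row)
    columns = [
        "condition", "field_id", "acinus_id", "area_px", "centroid_row", "centroid_col",
        "wavr", "excluded_reason", *rp_cols, "rp_index", "sign",
    ]
    return pd.DataFrame(rows, columns=columns)
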