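"""Blind-scoring manifest: randomized, condition-withheld acinus crops.

Supervised (visual) scoring must be blind to the treatment condition.  The
retained acini of a dataset are exported as per-acinus crop images under
randomized numeric names, listed in a manifest whose order is a seeded
random permutation and which carries no condition information; a separate
key file maps crop ids back to (condition, field, acinus) so external
scores can be merged afterwards.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .overlay import _to_gray8
from .pipeline import FieldAnalysis

__all__ = ["write_blind_manifest", "merge_scores"]

CROP_MARGIN = 5


def write_blind_manifest(
    analyses: list[FieldAnalysis], seed: int, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export randomized crops + manifest and key tables.

    Writes ``manifest.csv`` (crop_id, nuclear_crop, polarity_crop — no
    condition column), ``manifest_key.csv`` (crop_id -> condition,
    field_id, acinus_id, rp_index) and the crop PNGs under ``crops/``.
    Raises if the dataset retains no acini.
    """
    out_dir = Path(out_dir)
    items = []
    for fa in analyses:
        by_id = {res.acinus_id: res for res in fa.results}
        for roi in fa.rois:
            if roi.retained and roi.acinus_id in by_id:
                items.append((fa, roi, by_id[roi.acinus_id]))
    if not items:
        raise ValueError("no retained acini: nothing to score")

    order = np.random.default_rng(seed).permutation(len(items))
    crops_dir = out_dir / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows, key_rows = [], []
    for rank, idx in enumerate(order):
        fa, roi, res = items[idx]
        crop_id = f"{rank:05d}"
        r0, c0, r1, c1 = roi.bbox
        h, w = fa.pair.nuclear.shape
        r0, c0 = max(0, r0 - CROP_MARGIN), max(0, c0 - CROP_MARGIN)
        r1, c1 = min(h, r1 + CROP_MARGIN), min(w, c1 + CROP_MARGIN)
        paths = {}
        for channel in ("nuclear", "polarity"):
            crop = getattr(fa.pair, channel).pixels[r0:r1, c0:c1]
            path = crops_dir / f"{crop_id}_{channel}.png"
            Image.fromarray(_to_gray8(crop)).save(path)
            paths[channel] = str(path.relative_to(out_dir))
        manifest_rows.append(
            {"crop_id": crop_id, "nuclear_crop": paths["nuclear"], "polarity_crop": paths["polarity"]}
        )
        key_rows.append(
            {
                "crop_id": crop_id,
                "condition": fa.pair.condition,
                "field_id": fa.pair.field_id,
                "acinus_id": roi.acinus_id,
                "rp_index": res.rp_index,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    key = pd.DataFrame(key_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    key.to_csv(out_dir / "manifest_key.csv", index=False)
    return manifest, key


def merge_scores(scores: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Join external visual scores (crop_id, score) back to provenance."""
    return scores.merge(key, on="crop_id", how="inner", validate="one_to_one")
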