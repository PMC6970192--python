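"""Dataset discovery for condition-organized image pairs.

A dataset is a directory with one subfolder per experimental condition; every
field of view contributes two files, a nuclear-stain channel and a
polarity-marker channel, told apart by a filename suffix (defaults
``_dapi`` / ``_pol``).  The pair is the unit the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .raster import ImageRaster, read_raster

__all__ = ["ChannelNaming", "FieldPair", "DatasetError", "discover_dataset"]

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")


class DatasetError(ValueError):
    """Malformed dataset layout (orphan channels, shape mismatches...)."""


@dataclass
class ChannelNaming:
    """Filename-suffix convention identifying the two channels."""

    nuclear_suffix: str = "_dapi"
    polarity_suffix: str = "_pol"


@dataclass
class FieldPair:
    """One imaged field: matched nuclear and polarity rasters."""

    condition: str
    field_id: str
    nuclear: ImageRaster
    polarity: ImageRaster

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.polarity.shape:
            raise DatasetError(
                f"field {self.condition}/{self.field_id}: nuclear shape "
                f"{self.nuclear.shape} != polarity shape {self.polarity.shape}"
            )


def _scan_condition(folder: Path, naming: ChannelNaming) -> list[tuple[str, Path, Path]]:
    nuclear: dict[str, Path] = {}
    polarity: dict[str, Path] = {}
    for f in sorted(folder.iterdir()):
        if not f.is_file() or f.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        stem = f.stem
        if stem.endswith(naming.nuclear_suffix):
            nuclear[stem[: -len(naming.nuclear_suffix)]] = f
        elif stem.endswith(naming.polarity_suffix):
            polarity[stem[: -len(naming.polarity_suffix)]] = f
    orphans = sorted(
        [str(nuclear[k]) for k in nuclear.keys() - polarity.keys()]
        + [str(polarity[k]) for k in polarity.keys() - nuclear.keys()]
    )
    if orphans:
        raise DatasetError(
            f"condition {folder.name!r}: unmatched channel files: " + ", ".join(orphans)
        )
    return [(fid, nuclear[fid], polarity[fid]) for fid in sorted(nuclear)]


def discover_dataset(
    root_dir: str | Path, naming: ChannelNaming | None = None
) -> list[FieldPair]:
    """Discover all field pairs under ``root_dir``, sorted by (condition, field).

    Raises :class:`DatasetError` if a channel file lacks its partner or a
    pair's dimensions disagree.  Discovery is deterministic: the same tree
    always yields the same ordering.
    """
    naming = naming or ChannelNaming()
    root = Path(root_dir)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} is not a directory")
    pairs: list[FieldPair] = []
    for cond_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for field_id, nuc_path, pol_path in _scan_condition(cond_dir, naming):
            pair = FieldPair(
                condition=cond_dir.name,
                field_id=field_id,
                nuclear=read_raster(nuc_path),
                polarity=read_raster(pol_path),
            )
            pair.nuclear.check_analyzable()
            pairs.append(pair)
    return pairs
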