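"""Run configuration: analysis parameters, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Parameters of one analysis run; persisted verbatim with the outputs.

    ``wavr_cutoff`` accepts a number or the string ``"auto"``, in which case
    the cutoff is chosen from the pooled WAVR distribution of the dataset
    (two-component fit, equal-density intersection).
    """

    nuclear_suffix: str = "_dapi"
    polarity_suffix: str = "_pol"
    n_terraces: int = 8
    min_area: int = 300
    max_area: int = 10000
    dilation_radius: int = 3
    border_smooth_radius: int = 2
    fill_holes: bool = True
    seed_suppression_depth: float = 2.0
    wavr_cutoff: float | str = 0.8
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_terraces < 2:
            raise ValueError("n_terraces must be >= 2")
        if self.min_area < 1 or self.min_area > self.max_area:
            raise ValueError("need 1 <= min_area <= max_area")
        for name in ("dilation_radius", "border_smooth_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed_suppression_depth < 0:
            raise ValueError("seed_suppression_depth must be >= 0")
        if isinstance(self.wavr_cutoff, str):
            if self.wavr_cutoff != "auto":
                raise ValueError("wavr_cutoff must be a number or 'auto'")
        elif self.wavr_cutoff < 0:
            raise ValueError("wavr_cutoff must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
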