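"""Pipeline configuration.

Defaults are the published operating point of the method: Gaussian
σ = 15 px on a 128×256 sagittal grid, localization windows
[1000, 2000] / [400, 500] / [800, 1900] HU, L1 segmentation window
[-1024, 500] HU, L3 windows [-1024, 2048] / [-190, -30] / [40, 100] HU,
512×512 slice grid and k = 5 cross-validation.  Serializes to YAML and
supports dotted ``key=value`` overrides from the command line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # geometry
    isotropic_spacing: float = 1.0          # mm
    projection: str = "mip"                 # "mip" | "mean"
    slab_fraction: float = 0.5
    localization_grid: tuple[int, int] = (128, 256)
    slice_grid: int = 512
    # HU windows
    localization_windows: tuple = ((1000, 2000), (400, 500), (800, 1900))
    l1_window: tuple = (-1024, 500)
    l3_windows: tuple = ((-1024, 2048), (-190, -30), (40, 100))
    # heatmap
    sigma: float = 15.0
    # model / training hyperparameters
    localizer_base_filters: int = 4
    localizer_epochs: int = 20
    localizer_batch_size: int = 4
    localizer_lr: float = 2e-3
    segmenter_base_filters: int = 8
    segmenter_epochs: int = 40
    segmenter_batch_size: int = 4
    segmenter_lr: float = 2e-3
    val_fraction: float = 0.0
    patience: int = 0
    # evaluation
    k: int = 5
    seed: int = 0

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def _tupled(v):
            return tuple(_tupled(x) for x in v) if isinstance(v, (list, tuple)) else v

        return cls(**{k: _tupled(v) for k, v in d.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        """Apply {"field": value} or {"field": "parsed yaml"} overrides."""
        parsed = {}
        for key, value in overrides.items():
            if key not in self.__dataclass_fields__:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(value, str):
                value = yaml.safe_load(value)
            if isinstance(value, list):
                value = tuple(tuple(x) if isinstance(x, list) else x for x in value)
            parsed[key] = value
        return replace(self, **parsed)

    def digest(self) -> str:
        """Stable hash of the configuration (for model manifests)."""
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
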