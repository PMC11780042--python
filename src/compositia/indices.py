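"""Body-composition indices from segmented L1/L3 slices.

Seven indices are reported per subject:

* L1 trabecular BMD average (HU) — mean HU over the trabecular mask;
* L1 trabecular BMD standard deviation (HU);
* L1 trabecular bone area (cm²);
* L3 SAT area (cm²);
* L3 SMA — skeletal muscle area (cm²);
* L3 VAT area (cm²);
* L3 SAT density standard deviation (HU).

Density statistics always use the original HU slice, never windowed
values, and the population standard deviation (divide by N).  The
cortical class contributes to no index.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .segmentation import LabelMask

INDEX_COLUMNS = [
    "bmd_avg", "bmd_sd", "l1_trab_area",
    "l3_sat_area", "l3_sma", "l3_vat_area", "l3_sat_density_sd",
]


class UndefinedStatisticError(ValueError):
    """Raised when a density statistic is requested over an empty region."""


@dataclass
class IndexReport:
    bmd_avg: float            # HU
    bmd_sd: float             # HU
    l1_trab_area: float       # cm^2
    l3_sat_area: float        # cm^2
    l3_sma: float             # cm^2
    l3_vat_area: float        # cm^2
    l3_sat_density_sd: float  # HU
    subject_id: str = ""

    def __post_init__(self):
        for name in ("l1_trab_area", "l3_sat_area", "l3_sma", "l3_vat_area",
                     "bmd_sd", "l3_sat_density_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])[["subject_id", *INDEX_COLUMNS]]

    def values(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in INDEX_COLUMNS], dtype=float)


def region_area(mask: LabelMask, class_name: str, spacing: tuple[float, float]) -> float:
    """Area of one class in cm²: pixel count × spacing_x × spacing_y / 100."""
    n = int(mask.binary(class_name).sum())
    return n * spacing[0] * spacing[1] / 100.0


def region_density_stats(mask: LabelMask, class_name: str, hu: np.ndarray) -> tuple[float, float]:
    """(mean, population sd) of HU over one class region; empty region raises."""
    if hu.shape != mask.labels.shape:
        raise ValueError("HU slice and mask shapes differ")
    sel = hu[mask.binary(class_name)]
    if sel.size == 0:
        raise UndefinedStatisticError(
            f"density statistics undefined: empty {class_name!r} region")
    return float(sel.mean()), float(sel.std(ddof=0))


def compute_report(l1_mask: LabelMask, l1_hu: np.ndarray,
                   l3_mask: LabelMask, l3_hu: np.ndarray,
                   spacing: tuple[float, float], subject_id: str = "") -> IndexReport:
    """All seven indices from the two labelled slices and their HU images."""
    bmd_avg, bmd_sd = region_density_stats(l1_mask, "trabecular", l1_hu)
    _, sat_sd = region_density_stats(l3_mask, "sat", l3_hu)
    return IndexReport(
        bmd_avg=bmd_avg,
        bmd_sd=bmd_sd,
        l1_trab_area=region_area(l1_mask, "trabecular", spacing),
        l3_sat_area=region_area(l3_mask, "sat", spacing),
        l3_sma=region_area(l3_mask, "sma", spacing),
        l3_vat_area=region_area(l3_mask, "vat", spacing),
        l3_sat_density_sd=sat_sd,
        subject_id=subject_id,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Concatenate per-subject reports into one table (batch mode)."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
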