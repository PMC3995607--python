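"""Lung dose-volume metrics: mean lung dose and Vx threshold volumes.

``Vx`` is the percentage of the lung ROI receiving a dose strictly above
``x`` Gy (or CGE) — the strict inequality follows the planning convention
"irradiated to above x".  Proton physical dose is converted to ⁶⁰Co Gray
Equivalents by a constant relative biological effectiveness factor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ImageVolume, Modality, ModalityError, ensure_same_grid

DEFAULT_THRESHOLDS = (5.0, 10.0, 20.0, 30.0)
DEFAULT_RBE = 1.1


@dataclass(frozen=True)
class DoseMetrics:
    """Mean lung dose plus V5/V10/V20/V30 (percent of ROI volume)."""

    mld: float
    v5: float
    v10: float
    v20: float
    v30: float
    unit: str = "Gy"

    def __post_init__(self) -> None:
        vs = (self.v5, self.v10, self.v20, self.v30)
        if any(not 0 <= v <= 100 for v in vs):
            raise ValueError("Vx metrics must be in [0, 100]")
        if not (self.v5 >= self.v10 >= self.v20 >= self.v30):
            raise ValueError("Vx must be non-increasing in the threshold")
        if self.mld < 0:
            raise ValueError("mld must be >= 0")

    def as_row(self) -> dict:
        return {"mld": self.mld, "v5": self.v5, "v10": self.v10,
                "v20": self.v20, "v30": self.v30, "dose_unit": self.unit}


def dose_metrics(dose: ImageVolume, roi: BinaryMask,
                 thresholds=DEFAULT_THRESHOLDS) -> DoseMetrics:
    """Restrict the dose grid to the ROI and summarise it.

    ``mld`` is the mean dose over ROI voxels and each ``v_t`` the percentage
    of ROI voxels with dose strictly greater than ``t``.
    """
    if dose.modality is not Modality.DOSE:
        raise ModalityError(f"dose_metrics expects a DOSE volume, got {dose.modality.value}")
    ensure_same_grid(dose, roi)
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    vals = dose.data[roi.data]
    n_neg = int((vals < 0).sum())
    if n_neg:
        raise ValueError(f"dose grid contains {n_neg} negative voxels inside the ROI")
    vx = {t: 100.0 * float((vals > t).mean()) for t in thresholds}
    return DoseMetrics(mld=float(vals.mean()),
                       v5=vx[thresholds[0]], v10=vx[thresholds[1]],
                       v20=vx[thresholds[2]], v30=vx[thresholds[3]],
                       unit=dose.unit or "Gy")


def to_cge(dose: ImageVolume, rbe: float = DEFAULT_RBE) -> ImageVolume:
    """Convert a proton physical-dose grid (Gy) to ⁶⁰Co Gray Equivalents.

    Voxelwise multiplication by the RBE factor; a grid already tagged CGE is
    rejected so the conversion cannot be applied twice.
    """
    if dose.modality is not Modality.DOSE:
        raise ModalityError(f"to_cge expects a DOSE volume, got {dose.modality.value}")
    if rbe <= 0:
        raise ValueError("rbe must be > 0")
    if dose.unit == "CGE":
        raise ValueError("dose is already in CGE; refusing to convert twice")
    return dose.with_data(dose.data * rbe, unit="CGE")
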