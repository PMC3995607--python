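"""Distributional uptake biomarkers over a lung ROI.

The biomarker panel is the mean, SD, maximum and the 80th/90th/95th
percentiles of the voxel-value distribution (SUV for PET, HU for CT) within
the segmented lung region of interest.  Percentiles are read off the empirical
cumulative distribution with linear interpolation between order statistics at
rank ``1 + (p/100)(n - 1)``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, ImageVolume, Modality, ModalityError, ensure_same_grid


def percentile(values, p: float, method: str = "linear") -> float:
    """The ``p``-th percentile of a collection of voxel values.

    Uses linear interpolation between order statistics by default; the
    estimator is exposed for sensitivity checks (any method accepted by
    :func:`numpy.percentile`).  ``p = 0`` returns the minimum and ``p = 100``
    the maximum.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot compute a percentile of an empty collection")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values contain non-finite entries")
    if not 0 <= p <= 100:
        raise ValueError(f"p must be in [0, 100], got {p}")
    return float(np.percentile(arr, p, method=method))


@dataclass(frozen=True)
class UptakeSummary:
    """Biomarker panel for one modality over one ROI."""

    modality: str            # "SUV" or "HU"
    mean: float
    sd: float
    max: float
    p80: float
    p90: float
    p95: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        tol = 1e-9 * max(1.0, abs(self.max))
        if not (self.p80 <= self.p90 + tol and self.p90 <= self.p95 + tol
                and self.p95 <= self.max + tol):
            raise ValueError("percentile panel must be ordered: p80 <= p90 <= p95 <= max")

    def as_row(self, case_id: str = "") -> dict:
        """One flat CSV-ready record."""
        prefix = self.modality.lower()
        row = {f"{prefix}_{k}": getattr(self, k)
               for k in ("mean", "sd", "max", "p80", "p90", "p95")}
        row[f"{prefix}_n_voxels"] = self.n_voxels
        if case_id:
            row = {"case_id": case_id, **row}
        return row


_MODALITY_LABEL = {Modality.PET_SUV: "SUV", Modality.CT_HU: "HU"}


def summarize_roi(volume: ImageVolume, roi: BinaryMask,
                  method: str = "linear") -> UptakeSummary:
    """Compute the biomarker panel over exactly the ROI voxels.

    The SD uses the ``n - 1`` denominator; a single-voxel ROI has its SD
    pinned to 0 with a warning.  Dose volumes are rejected (dose metrics live
    in :mod:`pulmopet.dosimetry`).
    """
    if volume.modality not in _MODALITY_LABEL:
        raise ModalityError(
            f"summarize_roi handles PET_SUV or CT_HU volumes, got {volume.modality.value}")
    ensure_same_grid(volume, roi)
    if roi.voxel_count == 0:
        raise ValueError("ROI is empty")
    vals = volume.data[roi.data]
    if vals.size == 1:
        warnings.warn("single-voxel ROI: SD is undefined, reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
    return UptakeSummary(
        modality=_MODALITY_LABEL[volume.modality],
        mean=float(vals.mean()),
        sd=sd,
        max=float(vals.max()),
        p80=percentile(vals, 80, method),
        p90=percentile(vals, 90, method),
        p95=percentile(vals, 95, method),
        n_voxels=int(vals.size),
    )
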