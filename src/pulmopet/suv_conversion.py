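"""Standardised uptake value (SUV) conversion with radioactive-decay correction.

SUV normalises a PET activity concentration by the injected activity per unit
body mass::

    SUV = activity [Bq/mL] * body weight [g] / decay-corrected injected dose [Bq]

The injected dose is decay-corrected from injection time to the start of the
scan using the radionuclide half-life (¹⁸F by default, 109.771 min).  Water-
equivalent tissue density (1 g/mL) makes the ratio dimensionless.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import ImageVolume, Modality, ModalityError

#: ¹⁸F physical half-life in minutes.
F18_HALF_LIFE_MIN = 109.771


@dataclass(frozen=True)
class AcquisitionMeta:
    """Per-scan acquisition metadata needed for SUV computation.

    Attributes
    ----------
    injected_dose_Bq
        Injected activity at injection time, in becquerel.
    injection_to_scan_min
        Minutes elapsed between injection and the start of the emission scan.
    body_weight_g
        Patient body mass in grams.
    half_life_min
        Radionuclide half-life in minutes (default ¹⁸F).
    """

    injected_dose_Bq: float
    injection_to_scan_min: float
    body_weight_g: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_dose_Bq <= 0:
            raise ValueError("injected_dose_Bq must be > 0")
        if self.injection_to_scan_min < 0:
            raise ValueError("injection_to_scan_min must be >= 0")
        if self.body_weight_g <= 0:
            raise ValueError("body_weight_g must be > 0")
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be > 0")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        return cls(**json.loads(Path(path).read_text()))


def decay_factor(meta: AcquisitionMeta) -> float:
    """Fraction of the injected activity remaining at scan start.

    Returns ``2 ** (-t / T½)`` for elapsed time ``t``; the decay-corrected
    dose is ``injected_dose_Bq * decay_factor(meta)``.
    """
    return float(2.0 ** (-meta.injection_to_scan_min / meta.half_life_min))


def activity_to_suv(pet: ImageVolume, meta: AcquisitionMeta, *,
                    input_unit: str = "Bq/mL") -> ImageVolume:
    """Convert a PET activity-concentration volume to SUV, voxelwise.

    Parameters
    ----------
    pet
        Volume tagged ``PET_ACTIVITY``.  A volume already tagged ``PET_SUV``
        is rejected rather than silently re-scaled.
    meta
        Acquisition metadata.
    input_unit
        ``"Bq/mL"`` (default) or ``"kBq/mL"``; the latter is converted
        explicitly before applying the SUV equation.
    """
    if pet.modality is not Modality.PET_ACTIVITY:
        raise ModalityError(
            f"activity_to_suv expects PET_ACTIVITY input, got {pet.modality.value}")
    if input_unit not in ("Bq/mL", "kBq/mL"):
        raise ValueError(f"unsupported activity unit {input_unit!r}")
    n_neg = int((pet.data < 0).sum())
    if n_neg:
        raise ValueError(f"PET volume contains {n_neg} negative activity voxels")
    activity = pet.data * (1000.0 if input_unit == "kBq/mL" else 1.0)
    corrected_dose = meta.injected_dose_Bq * decay_factor(meta)
    suv = activity * meta.body_weight_g / corrected_dose
    return pet.with_data(suv, modality=Modality.PET_SUV, unit="SUV")
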