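"""Shared voxel-grid containers for the PET/CT pneumonitis pipeline.

Axis convention: arrays are indexed ``(x, y, z)`` with ``x`` the left-right
axis, ``y`` anterior-posterior and ``z`` inferior-superior (higher ``z`` index
is more cranial).  Voxel indices are 0-based and the world position of a voxel
centre is ``origin + index * spacing``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class Modality(str, Enum):
    """What the voxel values of an :class:`ImageVolume` mean."""

    CT_HU = "CT_HU"
    PET_ACTIVITY = "PET_ACTIVITY"
    PET_SUV = "PET_SUV"
    DOSE = "DOSE"


class ModalityError(ValueError):
    """Raised when an operation receives a volume with the wrong modality tag."""


class GridMismatchError(ValueError):
    """Raised when two volumes/masks that must share a grid do not."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar field on a regular grid.

    Parameters
    ----------
    data
        3-D float array, axes ``(x, y, z)``.
    spacing
        Per-axis voxel size in millimetres.
    modality
        One of :class:`Modality`.
    origin
        World coordinate of voxel ``(0, 0, 0)`` in millimetres.
    unit
        Free-text unit tag; used for dose (``"Gy"`` vs ``"CGE"``) and PET
        activity (``"Bq/mL"`` or ``"kBq/mL"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {arr.ndim} dims")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, modality: Modality | None = None,
                  unit: str | None = None) -> "ImageVolume":
        """New volume on the same grid with replaced payload/tags."""
        return replace(self, data=data,
                       modality=self.modality if modality is None else modality,
                       unit=self.unit if unit is None else unit)

    # ---- NIfTI I/O -------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        """Write the volume as NIfTI plus a JSON sidecar with the tags."""
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), path)
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
            else path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"modality": self.modality.value, "unit": self.unit,
             "spacing_mm": list(self.spacing), "origin_mm": list(self.origin)}, indent=2))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, modality: Modality | str | None = None,
                   unit: str | None = None) -> "ImageVolume":
        path = Path(path)
        img = nib.load(path)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
            else path.with_suffix(".json")
        if modality is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            modality = meta.get("modality")
            unit = unit if unit is not None else meta.get("unit")
        if modality is None:
            raise ValueError(f"no modality given and no sidecar found for {path}")
        return cls(np.asarray(img.dataobj, dtype=float), spacing,
                   Modality(modality), origin, unit)


@dataclass
class BinaryMask:
    """Grid-aligned boolean field with a provenance trail.

    ``provenance`` is an ordered list of human-readable processing steps;
    every subtraction records the voxel delta it caused.
    """

    data: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def subtract(self, other: "BinaryMask", label: str) -> "BinaryMask":
        """Set difference, recording the step and its voxel delta."""
        ensure_same_grid(self, other)
        new = self.data & ~other.data
        delta = self.voxel_count - int(new.sum())
        return BinaryMask(new, self.provenance + [f"subtracted {label}: -{delta} voxels"])

    def to_nifti(self, path: str | Path, reference: ImageVolume | None = None) -> Path:
        path = Path(path)
        aff = reference.affine() if reference is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), aff), path)
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, provenance: list[str] | None = None) -> "BinaryMask":
        img = nib.load(Path(path))
        return cls(np.asarray(img.dataobj) > 0, provenance or [f"loaded from {Path(path).name}"])


def ensure_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless the two objects share a shape."""
    if tuple(a.shape) != tuple(b.shape):
        raise GridMismatchError(f"grid shapes differ: {tuple(a.shape)} vs {tuple(b.shape)}")


def resample_like(volume: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Trilinearly resample ``volume`` onto the grid of ``reference``.

    Returns ``volume`` unchanged when the grids already coincide.  Used to put
    PET or dose grids onto the CT grid before masking.
    """
    same = (volume.shape == reference.shape
            and np.allclose(volume.spacing, reference.spacing)
            and np.allclose(volume.origin, reference.origin))
    if same:
        return volume
    idx = np.indices(reference.shape, dtype=float)
    coords = [(idx[i] * reference.spacing[i] + reference.origin[i] - volume.origin[i])
              / volume.spacing[i] for i in range(3)]
    data = ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    return ImageVolume(data, reference.spacing, volume.modality, reference.origin, volume.unit)
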