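"""Core in-memory containers for CT anatomy, structures, plans and dose.

Conventions
-----------
* Voxel arrays are indexed ``(ix, iy, iz)`` with 0-based indices.
* Room coordinates are in millimetres, DICOM patient axes (x to patient
  left, y posterior, z superior).  ``origin`` is the position of the
  corner of voxel ``(0, 0, 0)``; the centre of voxel ``i`` is at
  ``origin + (i + 0.5) * spacing``.
* Gantry angles follow IEC 61217: 0 deg means the beam enters from the
  anterior, increasing clockwise when viewed from the patient's feet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical structure order used throughout the package.
CANONICAL_STRUCTURES = (
    "body",
    "TLV",
    "PGTV",
    "duodenum",
    "stomach",
    "esophagus",
    "heart",
    "spleen",
)

#: Organs-at-risk (canonical structures minus body/target/liver host).
OAR_STRUCTURES = ("duodenum", "stomach", "esophagus", "heart", "spleen")


@dataclass
class VolumeGrid:
    """A 3-D HU volume with its geometric placement.

    Parameters
    ----------
    voxels
        HU values, shape ``(nx, ny, nz)``.
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        Room-coordinate position (mm) of the corner of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive components")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Room coordinates of voxel centres along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map room coordinates (``(..., 3)`` mm) to fractional voxel indices.

        Index ``i`` corresponds to the centre of voxel ``i`` so that
        interpolation with ``scipy.ndimage.map_coordinates`` samples voxel
        centres exactly at integer indices.
        """
        pts = np.asarray(points_mm, dtype=float)
        return (pts - self.origin) / self.spacing - 0.5


@dataclass
class StructureSet:
    """Binary masks for the eight canonical structures on a grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in CANONICAL_STRUCTURES if n not in self.masks]
        if missing:
            raise MissingStructureError(missing)
        ordered = {}
        shape = None
        for name in CANONICAL_STRUCTURES:
            m = np.asarray(self.masks[name]).astype(bool)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} differs from {shape}"
                )
            ordered[name] = m
        self.masks = ordered

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> tuple[str, ...]:
        return CANONICAL_STRUCTURES


class MissingStructureError(KeyError):
    """Raised when canonical structures are absent from an input."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "missing canonical structure(s): " + ", ".join(self.missing)
        )


@dataclass
class PatientCase:
    """One case: CT volume, structures, isocenter and clinical angles."""

    case_id: str
    volume: VolumeGrid
    structures: StructureSet
    isocenter: np.ndarray
    clinical_angles: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        if self.isocenter.shape != (3,):
            raise ValueError("isocenter must be a 3-vector (mm)")
        self.clinical_angles = [float(a) % 360.0 for a in self.clinical_angles]
        for name, mask in self.structures.masks.items():
            if mask.shape != self.volume.shape:
                raise ValueError(
                    f"mask {name!r} shape {mask.shape} != volume {self.volume.shape}"
                )


@dataclass
class DoseGrid:
    """Dose in % of prescription, aligned to a reference VolumeGrid."""

    dose: np.ndarray
    prescription_level: float = 100.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")
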