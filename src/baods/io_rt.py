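"""Read/write DICOM-RT objects (CT series, RTSTRUCT, RTPLAN, RTDOSE).

This replaces TPS-side scripting: cases are pulled straight from the
standard DICOM-RT files into :class:`~baods.containers.PatientCase`.
Contours are rasterized per slice with even-odd polygon fill (standard
RTSTRUCT semantics: nested contours toggle membership), and masks are
converted back to closed planar contours through the 0.5 iso-level of
the mask.

A lightweight internal container (a directory of ``.npy`` arrays plus a
JSON sidecar) is provided for fast intermediate storage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates
from skimage.draw import polygon2mask
from skimage.measure import find_contours

from .containers import (
    CANONICAL_STRUCTURES,
    DoseGrid,
    MissingStructureError,
    PatientCase,
    StructureSet,
    VolumeGrid,
)

# Case-insensitive aliases mapping clinical ROI names to canonical names.
DEFAULT_ALIASES = {
    "body": "body",
    "external": "body",
    "skin": "body",
    "tlv": "TLV",
    "liver": "TLV",
    "total liver volume": "TLV",
    "pgtv": "PGTV",
    "gtv": "PGTV",
    "ptv": "PGTV",
    "duodenum": "duodenum",
    "stomach": "stomach",
    "esophagus": "esophagus",
    "oesophagus": "esophagus",
    "heart": "heart",
    "spleen": "spleen",
}

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"


class NonUniformSpacingError(ValueError):
    """CT slices do not form a uniformly spaced series."""

    def __init__(self, spacings: np.ndarray):
        self.spacings = np.asarray(spacings)
        super().__init__(
            f"non-uniform slice spacing; measured gaps (mm): {self.spacings}"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_ct_series(ct_path: str | Path) -> VolumeGrid:
    paths = sorted(Path(ct_path).glob("*.dcm"))
    slices = []
    for p in paths:
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise FileNotFoundError(f"no CT slices found under {ct_path}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.ptp(gaps) > 1e-3:
            raise NonUniformSpacingError(gaps)
        dz = float(gaps[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    ipp = np.array([float(v) for v in first.ImagePositionPatient])
    spacing = np.array([dx, dy, dz])
    # ImagePositionPatient is the centre of the first voxel
    origin = ipp - 0.5 * spacing
    hu = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu.append(arr * slope + intercept)
    vol = np.stack(hu, axis=-1)          # (ny, nx, nz) rows=y, cols=x
    vol = np.ascontiguousarray(np.swapaxes(vol, 0, 1))  # (nx, ny, nz)
    if np.allclose(vol, np.round(vol)):
        vol = np.round(vol).astype(np.int16)
    return VolumeGrid(vol, spacing, origin)


def rasterize_contours(
    contours_mm: list[np.ndarray], grid: VolumeGrid
) -> np.ndarray:
    """Rasterize closed planar contours (mm) to a voxel mask (even-odd fill).

    Each contour is an ``(n, 3)`` array of room coordinates lying in a
    single axial plane; contours landing on the same slice toggle
    membership (XOR), which implements even-odd semantics for nested
    rings (e.g. holes).
    """
    nx, ny, nz = grid.shape
    mask = np.zeros((nx, ny, nz), dtype=bool)
    for pts in contours_mm:
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < 3:
            continue
        idx = grid.mm_to_index(pts)
        k = int(np.round(np.mean(idx[:, 2])))
        if k < 0 or k >= nz:
            continue
        poly = idx[:, :2]  # (x_idx, y_idx) == (row, col) of the (nx,ny) slice
        m2d = polygon2mask((nx, ny), poly)
        mask[:, :, k] ^= m2d
    return mask


def _structure_contours(ds: Dataset) -> dict[str, list[np.ndarray]]:
    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    out: dict[str, list[np.ndarray]] = {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber))
        if name is None:
            continue
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData])
            contours.append(data.reshape(-1, 3))
        out[name] = contours
    return out


def read_case(
    ct_path: str | Path,
    rtstruct_path: str | Path,
    rtplan_path: str | Path,
    aliases: dict[str, str] | None = None,
    case_id: str | None = None,
) -> PatientCase:
    """Assemble a :class:`PatientCase` from DICOM CT + RTSTRUCT + RTPLAN.

    ROI names are matched case-insensitively through ``aliases`` (falling
    back to :data:`DEFAULT_ALIASES`); a missing canonical structure raises
    :class:`~baods.containers.MissingStructureError` naming the absentees.
    """
    alias = {k.lower(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    grid = _read_ct_series(ct_path)
    struct_ds = pydicom.dcmread(rtstruct_path)
    contours = _structure_contours(struct_ds)

    masks: dict[str, np.ndarray] = {}
    for roi_name, roi_contours in contours.items():
        canon = alias.get(roi_name.lower())
        if canon is None and roi_name in CANONICAL_STRUCTURES:
            canon = roi_name
        if canon is None:
            continue
        masks[canon] = rasterize_contours(roi_contours, grid)
    missing = [n for n in CANONICAL_STRUCTURES if n not in masks]
    if missing:
        raise MissingStructureError(missing)

    plan_ds = pydicom.dcmread(rtplan_path)
    angles: list[float] = []
    isocenter = None
    beam_seq = getattr(plan_ds, "BeamSequence", None) or getattr(
        plan_ds, "IonBeamSequence", []
    )
    for beam in beam_seq:
        cp = beam.ControlPointSequence[0]
        angles.append(float(cp.GantryAngle) % 360.0)
        if isocenter is None and hasattr(cp, "IsocenterPosition"):
            isocenter = np.array([float(v) for v in cp.IsocenterPosition])
    if isocenter is None:
        # plan without beams: fall back to the target centroid
        idx = np.argwhere(masks["PGTV"])
        isocenter = grid.origin + (idx.mean(axis=0) + 0.5) * grid.spacing

    if case_id is None:
        case_id = str(getattr(plan_ds, "PatientID", "case"))
    return PatientCase(case_id, grid, StructureSet(masks), isocenter, angles)


def read_dose(
    rtdose_path: str | Path,
    reference: VolumeGrid,
    prescription_gy: float | None = None,
) -> DoseGrid:
    """Read an RTDOSE file and resample it (trilinear) onto ``reference``.

    Dose stored in Gy is converted to % of ``prescription_gy``; dose with
    ``DoseUnits == 'RELATIVE'`` is taken to be % already.
    """
    ds = pydicom.dcmread(rtdose_path)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    dose = ds.pixel_array.astype(np.float64) * scaling  # (nz, ny, nx)
    dose = np.ascontiguousarray(dose.transpose(2, 1, 0))  # (nx, ny, nz)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offs = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offs[1] - offs[0]) if len(offs) > 1 else 1.0
    ipp = np.array([float(v) for v in ds.ImagePositionPatient])
    spacing = np.array([dx, dy, dz])
    src = VolumeGrid(np.zeros((1, 1, 1)), spacing, ipp - 0.5 * spacing)

    lo_src = src.origin
    hi_src = src.origin + np.array(dose.shape) * spacing
    lo_ref = reference.origin
    hi_ref = reference.origin + np.array(reference.shape) * reference.spacing
    if np.any(hi_src <= lo_ref) or np.any(lo_src >= hi_ref):
        raise ValueError("dose grid does not overlap the reference grid")

    if dose.shape == reference.shape and np.allclose(
        src.origin, reference.origin
    ) and np.allclose(spacing, reference.spacing):
        resampled = dose
    else:
        axes = [reference.voxel_centers_axis(a) for a in range(3)]
        pts = np.stack(
            np.meshgrid(*axes, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        coords = ((pts - src.origin) / spacing - 0.5).T
        resampled = map_coordinates(
            dose, coords, order=1, mode="constant", cval=0.0
        ).reshape(reference.shape)

    if str(getattr(ds, "DoseUnits", "GY")).upper() != "RELATIVE":
        if prescription_gy is None:
            raise ValueError(
                "dose is in Gy; prescription_gy is required to convert to %"
            )
        resampled = 100.0 * resampled / prescription_gy
    return DoseGrid(np.clip(resampled, 0.0, None))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _base_dataset(sop_class: str, modality: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    return ds


def mask_to_contours(mask: np.ndarray, grid: VolumeGrid) -> list[np.ndarray]:
    """Closed planar contours (mm) through the 0.5 iso-level of a mask."""
    out = []
    zc = grid.voxel_centers_axis(2)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        # pad so regions touching the border still yield closed contours
        padded = np.pad(sl.astype(float), 1)
        for c in find_contours(padded, 0.5):
            c = c - 1.0
            pts = np.empty((len(c), 3))
            pts[:, 0] = grid.origin[0] + (c[:, 0] + 0.5) * grid.spacing[0]
            pts[:, 1] = grid.origin[1] + (c[:, 1] + 0.5) * grid.spacing[1]
            pts[:, 2] = zc[k]
            out.append(pts)
    return out


def write_case(case: PatientCase, path: str | Path) -> None:
    """Emit a DICOM CT series + RTSTRUCT + RTPLAN re-readable by read_case."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = case.volume
    nx, ny, nz = grid.shape
    frame_uid = generate_uid()
    series_uid = generate_uid()

    hu = np.asarray(grid.voxels)
    hu_int = np.round(hu).astype(np.int16)
    for k in range(nz):
        ds = _base_dataset(_CT_SOP, "CT")
        ds.PatientID = case.case_id
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        center0 = grid.origin + 0.5 * grid.spacing
        ds.ImagePositionPatient = [
            float(center0[0]),
            float(center0[1]),
            float(center0[2] + k * grid.spacing[2]),
        ]
        ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
        ds.SliceThickness = float(grid.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.ascontiguousarray(hu_int[:, :, k].T).tobytes()
        ds.save_as(path / f"ct_{k:04d}.dcm", enforce_file_format=True)

    # RTSTRUCT
    ss = _base_dataset(_RTSTRUCT_SOP, "RTSTRUCT")
    ss.PatientID = case.case_id
    ss.StructureSetLabel = "baods"
    ss.StructureSetROISequence = []
    ss.ROIContourSequence = []
    for num, name in enumerate(CANONICAL_STRUCTURES, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ss.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for pts in mask_to_contours(case.structures[name], grid):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(v) for v in pts.reshape(-1)]
            rc.ContourSequence.append(c)
        ss.ROIContourSequence.append(rc)
    ss.save_as(path / "rtstruct.dcm", enforce_file_format=True)

    # RTPLAN
    plan = _base_dataset(_RTPLAN_SOP, "RTPLAN")
    plan.PatientID = case.case_id
    plan.RTPlanLabel = "baods"
    plan.BeamSequence = []
    for i, angle in enumerate(case.clinical_angles, start=1):
        beam = Dataset()
        beam.BeamNumber = i
        beam.BeamName = f"field{i}"
        beam.BeamType = "STATIC"
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = float(angle)
        cp.IsocenterPosition = [float(v) for v in case.isocenter]
        beam.ControlPointSequence = [cp]
        plan.BeamSequence.append(beam)
    plan.save_as(path / "rtplan.dcm", enforce_file_format=True)


def write_dose(
    dose: DoseGrid, reference: VolumeGrid, path: str | Path
) -> None:
    """Write a DoseGrid (in %) as a RELATIVE-units RTDOSE file."""
    ds = _base_dataset(_RTDOSE_SOP, "RTDOSE")
    arr = np.asarray(dose.dose, dtype=float)
    scaling = max(arr.max(), 1e-12) / (2**31 - 1)
    quant = np.round(arr / scaling).astype(np.uint32)
    ds.DoseUnits = "RELATIVE"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    nx, ny, nz = arr.shape
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    center0 = reference.origin + 0.5 * reference.spacing
    ds.ImagePositionPatient = [float(v) for v in center0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(reference.spacing[1]), float(reference.spacing[0])]
    ds.GridFrameOffsetVector = [
        float(k * reference.spacing[2]) for k in range(nz)
    ]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(
        quant.transpose(2, 1, 0)
    ).tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# internal container
# ---------------------------------------------------------------------------

def save_case_npz(case: PatientCase, path: str | Path) -> None:
    """Serialize a case as raw arrays + a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "hu.npy", case.volume.voxels)
    for name in CANONICAL_STRUCTURES:
        np.save(path / f"mask_{name}.npy", case.structures[name])
    meta = {
        "case_id": case.case_id,
        "spacing": case.volume.spacing.tolist(),
        "origin": case.volume.origin.tolist(),
        "isocenter": case.isocenter.tolist(),
        "clinical_angles": list(case.clinical_angles),
        "structure_order": list(CANONICAL_STRUCTURES),
    }
    (path / "case.json").write_text(json.dumps(meta, indent=1))


def load_case_npz(path: str | Path) -> PatientCase:
    path = Path(path)
    meta = json.loads((path / "case.json").read_text())
    grid = VolumeGrid(
        np.load(path / "hu.npy"),
        np.asarray(meta["spacing"]),
        np.asarray(meta["origin"]),
    )
    masks = {
        name: np.load(path / f"mask_{name}.npy")
        for name in CANONICAL_STRUCTURES
    }
    return PatientCase(
        meta["case_id"],
        grid,
        StructureSet(masks),
        np.asarray(meta["isocenter"]),
        meta["clinical_angles"],
    )
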