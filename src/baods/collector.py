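"""Beam's-eye-view geometric feature collector.

For each gantry angle a fan of 25 parallel rays is traced through the
CT volume: one central ray through the isocenter plus 12 rays on each of
two ellipses (semi-axes 1/3 and 2/3 of the target's BEV half-extents)
placed on the PGTV cross-section in the isocenter plane. Each ray spans
1,000 mm divided into 4,000 bins of 0.25 mm pitch, ordered from the
source side toward the isocenter, and collects nine features per bin:
the Z-score-normalized HU (trilinear interpolation) and the binary
membership of the eight canonical structures (nearest-voxel lookup).

Sampling every 2 degrees from 0 to 358 yields the assembled input array
of 180 x 25 x 9 = 40,500 rows by 4,000 columns, laid out feature-fastest
(row = angle*225 + ray*9 + feature).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .containers import CANONICAL_STRUCTURES, PatientCase

RAY_LENGTH_MM = 1000.0
N_BINS = 4000
N_RAYS = 25
N_FEATURES = 9  # HU + 8 structure channels
RAYS_PER_ELLIPSE = 12
ELLIPSE_SCALES = (1.0 / 3.0, 2.0 / 3.0)
AIR_HU = -1000.0

#: Feature-row order within one ray block.
FEATURE_ORDER = ("HU",) + CANONICAL_STRUCTURES


def beam_direction(gantry_deg: float) -> np.ndarray:
    """Unit vector from source toward isocenter (IEC 61217, coplanar).

    Gantry 0: beam travels anterior -> posterior (+y); gantry 90: from the
    patient's left (-x travel).
    """
    g = np.deg2rad(gantry_deg)
    return np.array([-np.sin(g), np.cos(g), 0.0])


def bev_basis(gantry_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis of the beam's-eye view.

    Returns (lateral, up): ``up`` is the patient superior axis; ``lateral``
    completes a right-handed frame with the beam direction.
    """
    g = np.deg2rad(gantry_deg)
    lateral = np.array([np.cos(g), np.sin(g), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    return lateral, up


@dataclass
class Ray:
    """A single collector ray.

    ``end`` is the isocenter-side endpoint (mm); the ray starts
    ``length`` mm up-beam of it. Bin k's centre lies at distance
    (k + 0.5) * length / n_bins from the source-side start.
    """

    end: np.ndarray
    direction: np.ndarray
    length: float = RAY_LENGTH_MM
    n_bins: int = N_BINS

    def __post_init__(self) -> None:
        self.end = np.asarray(self.end, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("ray direction must be a unit vector")

    @property
    def pitch(self) -> float:
        return self.length / self.n_bins

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 3) room coordinates, source side first."""
        start = self.end - self.length * self.direction
        t = (np.arange(self.n_bins) + 0.5) * self.pitch
        return start[None, :] + t[:, None] * self.direction[None, :]


@dataclass
class FeatureBlock:
    """9 x n_bins feature array for a single ray."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != N_FEATURES:
            raise ValueError("FeatureBlock must be 9 x n_bins")


@dataclass
class FeatureTensor:
    """Assembled network input: (n_angles*25*9) rows x n_bins columns."""

    values: np.ndarray
    angle_list: np.ndarray
    case_id: str = ""
    n_rays: int = N_RAYS
    n_features: int = N_FEATURES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.angle_list = np.asarray(self.angle_list, dtype=float)
        expect = len(self.angle_list) * self.n_rays * self.n_features
        if self.values.shape[0] != expect:
            raise ValueError(
                f"row count {self.values.shape[0]} != "
                f"{len(self.angle_list)} angles x {self.n_rays} x {self.n_features}"
            )

    def block(self, angle_index: int, ray_index: int) -> np.ndarray:
        """The 9 x n_bins block for (angle, ray)."""
        base = (angle_index * self.n_rays + ray_index) * self.n_features
        return self.values[base : base + self.n_features]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        header = {
            "angle_list": self.angle_list.tolist(),
            "case_id": self.case_id,
            "n_rays": self.n_rays,
            "n_features": self.n_features,
            "layout": "row = angle*n_rays*n_features + ray*n_features + feature",
        }
        path.with_suffix(".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureTensor":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        return cls(
            np.load(path.with_suffix(".npy")),
            np.asarray(header["angle_list"]),
            header.get("case_id", ""),
            header.get("n_rays", N_RAYS),
            header.get("n_features", N_FEATURES),
        )


def bev_half_extents(
    case: PatientCase, gantry_deg: float
) -> tuple[float, float]:
    """Half-extents (mm) of the PGTV's axis-aligned BEV bounding box.

    The PGTV voxel centres are projected along the beam direction onto
    the isocenter plane; the box is axis-aligned in the (lateral, up)
    BEV basis. Degenerate extents fall back to one voxel with a warning.
    """
    grid = case.volume
    idx = np.argwhere(case.structures["PGTV"])
    if idx.size == 0:
        raise ValueError("PGTV mask is empty")
    pts = grid.origin + (idx + 0.5) * grid.spacing
    lateral, up = bev_basis(gantry_deg)
    rel = pts - case.isocenter
    u = rel @ lateral
    v = rel @ up
    a = 0.5 * (u.max() - u.min())
    b = 0.5 * (v.max() - v.min())
    vox = float(np.min(grid.spacing))
    if a < vox / 2 or b < vox / 2:
        warnings.warn(
            "degenerate PGTV BEV extent; falling back to 1-voxel radii",
            stacklevel=2,
        )
        a = max(a, vox)
        b = max(b, vox)
    return float(a), float(b)


def ray_fan(
    case: PatientCase,
    gantry_deg: float,
    length: float = RAY_LENGTH_MM,
    n_bins: int = N_BINS,
) -> list[Ray]:
    """The 25-ray parallel fan for one gantry angle.

    Ray 0 passes through the isocenter; rays 1-24 sit at 30-degree
    angular spacing (starting at BEV 'up') on two ellipses with semi-axes
    1/3 and 2/3 of the PGTV BEV half-extents. All rays are parallel to
    the central ray and end in the isocenter plane.
    """
    d = beam_direction(gantry_deg)
    lateral, up = bev_basis(gantry_deg)
    a, b = bev_half_extents(case, gantry_deg)
    rays = [Ray(case.isocenter.copy(), d, length, n_bins)]
    psi = np.deg2rad(np.arange(RAYS_PER_ELLIPSE) * 30.0)
    for s in ELLIPSE_SCALES:
        for p in psi:
            offset = s * (a * np.sin(p) * lateral + b * np.cos(p) * up)
            rays.append(Ray(case.isocenter + offset, d, length, n_bins))
    return rays


def znorm_stats(case: PatientCase) -> tuple[float, float]:
    """Per-patient HU mean and population SD (SD clamped to >= 1e-6)."""
    vox = np.asarray(case.volume.voxels, dtype=np.float64)
    mean = float(vox.mean())
    sd = float(vox.std())
    return mean, max(sd, 1e-6)


def _sample_features(
    case: PatientCase,
    points_mm: np.ndarray,
    hu_stats: tuple[float, float],
    mask_arrays: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Sample the 9 feature channels at arbitrary room points.

    Returns (9, n_points): channel 0 is the Z-scored HU (trilinear, air
    outside the volume), channels 1-8 binary masks (nearest voxel, 0
    outside).
    """
    mean, sd = hu_stats
    if sd < 1e-6:
        raise ValueError(
            "HU standard deviation below 1e-6; use znorm_stats (it clamps)"
        )
    grid = case.volume
    coords = grid.mm_to_index(points_mm).T  # (3, n)
    out = np.empty((N_FEATURES, points_mm.shape[0]), dtype=np.float32)
    hu = map_coordinates(
        np.asarray(grid.voxels, dtype=np.float32),
        coords,
        order=1,
        mode="constant",
        cval=AIR_HU,
    )
    out[0] = (hu - mean) / sd
    if mask_arrays is None:
        mask_arrays = {
            n: case.structures[n].astype(np.uint8)
            for n in CANONICAL_STRUCTURES
        }
    for i, name in enumerate(CANONICAL_STRUCTURES, start=1):
        out[i] = map_coordinates(
            mask_arrays[name], coords, order=0, mode="constant", cval=0
        )
    return out


def trace_ray(
    case: PatientCase, ray: Ray, hu_stats: tuple[float, float]
) -> FeatureBlock:
    """Collect the 9 x n_bins feature block along one ray."""
    return FeatureBlock(_sample_features(case, ray.bin_centers(), hu_stats))


def build_feature_tensor(
    case: PatientCase,
    angle_step: float = 2.0,
    n_bins: int = N_BINS,
    ray_length: float = RAY_LENGTH_MM,
) -> FeatureTensor:
    """Assemble the full network input over all sampled gantry angles.

    Normalization statistics are computed once per case; the binary
    structure rows are never normalized.
    """
    if 360.0 % angle_step != 0:
        raise ValueError("angle_step must divide 360")
    angles = np.arange(0.0, 360.0, angle_step)
    stats = znorm_stats(case)
    masks = {
        n: case.structures[n].astype(np.uint8) for n in CANONICAL_STRUCTURES
    }
    rows = np.empty(
        (len(angles) * N_RAYS * N_FEATURES, n_bins), dtype=np.float32
    )
    for ai, ang in enumerate(angles):
        fan = ray_fan(case, ang, ray_length, n_bins)
        pts = np.concatenate([r.bin_centers() for r in fan], axis=0)
        feats = _sample_features(case, pts, stats, masks)  # (9, 25*n_bins)
        block = feats.reshape(N_FEATURES, N_RAYS, n_bins)
        base = ai * N_RAYS * N_FEATURES
        rows[base : base + N_RAYS * N_FEATURES] = block.transpose(
            1, 0, 2
        ).reshape(N_RAYS * N_FEATURES, n_bins)
    return FeatureTensor(rows, angles, case.case_id)
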