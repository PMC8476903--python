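"""Synthetic abdominal phantoms for end-to-end testing.

Each phantom is a stack of ellipsoidal organs (body, liver = TLV, tumor
= PGTV inside the liver, and five organs-at-risk) painted with plausible
HU contrast over an air background, plus Gaussian CT noise. The
"clinical" gantry angles of a phantom are not random: they are derived
from the phantom's own geometry by a water-equivalent-path-length score
with an OAR-overshoot penalty, so the mapping from anatomy to target
ranking scores is learnable by the network.

HU values are rounded to integers (as in real CT data), which makes the
DICOM round-trip bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .collector import beam_direction, bev_basis, bev_half_extents
from .containers import (
    OAR_STRUCTURES,
    DoseGrid,
    PatientCase,
    StructureSet,
    VolumeGrid,
)
from .select_eval import select_angles
from .targets import SBeam

AIR_HU = -1000

# Plausible soft-tissue contrast (HU): enough signal for the features to
# carry anatomy without imitating any particular scanner.
DEFAULT_HU = {
    "body": 40,
    "TLV": 60,
    "PGTV": 55,
    "duodenum": 30,
    "stomach": 30,
    "esophagus": 30,
    "heart": 45,
    "spleen": 50,
}


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid: centre (mm, relative to grid centre) and
    semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


# Default organ layout (mm, relative to the grid centre), loosely an
# axial abdomen: liver right-anterior, stomach/spleen left, heart and
# esophagus superior.
DEFAULT_ORGANS = {
    "body": Ellipsoid((0, 0, 0), (150, 100, 90)),
    "TLV": Ellipsoid((55, -10, 0), (60, 50, 45)),
    "duodenum": Ellipsoid((15, 25, -25), (12, 12, 20)),
    "stomach": Ellipsoid((-40, 5, 0), (32, 24, 28)),
    "esophagus": Ellipsoid((-5, -25, 55), (8, 8, 25)),
    "heart": Ellipsoid((-20, -30, 55), (30, 26, 20)),
    "spleen": Ellipsoid((-70, -15, 10), (22, 16, 26)),
}


@dataclass
class PhantomConfig:
    """Full description of one synthetic case.

    ``tumor_offset`` places the PGTV relative to the liver centre; the
    noise SD (HU) emulates CT quantum noise inside the body.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    organs: dict[str, Ellipsoid] = field(
        default_factory=lambda: dict(DEFAULT_ORGANS)
    )
    tumor_offset: tuple[float, float, float] = (15.0, 0.0, 5.0)
    tumor_semi_axes: tuple[float, float, float] = (18.0, 15.0, 14.0)
    hu_values: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_HU))
    noise_sd: float = 15.0
    seed: int = 0
    case_id: str = "phantom"


class ContainmentError(ValueError):
    """Organ masks violate the required nesting (PGTV in TLV in body)."""


def _grid(config: PhantomConfig) -> VolumeGrid:
    shape = np.asarray(config.shape)
    spacing = np.asarray(config.spacing, dtype=float)
    origin = -0.5 * shape * spacing  # grid centred on the room origin
    return VolumeGrid(np.zeros(config.shape, dtype=np.int16), spacing, origin)


def _ellipsoid_mask(grid: VolumeGrid, ell: Ellipsoid) -> np.ndarray:
    axes = [grid.voxel_centers_axis(a) for a in range(3)]
    c = np.asarray(ell.center, dtype=float)
    s = np.asarray(ell.semi_axes, dtype=float)
    xx = ((axes[0] - c[0]) / s[0]) ** 2
    yy = ((axes[1] - c[1]) / s[1]) ** 2
    zz = ((axes[2] - c[2]) / s[2]) ** 2
    return (
        xx[:, None, None] + yy[None, :, None] + zz[None, None, :]
    ) <= 1.0


def _validate_containment(masks: dict[str, np.ndarray]) -> None:
    if np.any(masks["PGTV"] & ~masks["TLV"]):
        raise ContainmentError("PGTV is not contained in TLV")
    if np.any(masks["TLV"] & ~masks["body"]):
        raise ContainmentError("TLV is not contained in body")
    for name in OAR_STRUCTURES:
        if np.any(masks[name] & ~masks["body"]):
            raise ContainmentError(f"{name} is not contained in body")


def generate_case(config: PhantomConfig) -> PatientCase:
    """Build a phantom case; its clinical angles are geometry-derived.

    The HU volume is air (-1000) outside the body and per-organ HU plus
    rounded Gaussian noise inside. The isocenter is the PGTV centroid.
    """
    rng = np.random.default_rng(config.seed)
    grid = _grid(config)
    masks = {
        name: _ellipsoid_mask(grid, ell) for name, ell in config.organs.items()
    }
    tlv_c = np.asarray(config.organs["TLV"].center)
    masks["PGTV"] = _ellipsoid_mask(
        grid,
        Ellipsoid(
            tuple(tlv_c + np.asarray(config.tumor_offset)),
            config.tumor_semi_axes,
        ),
    )
    _validate_containment(masks)

    hu = np.full(config.shape, AIR_HU, dtype=np.float64)
    # paint large to small so the tumor/OARs override their hosts
    for name in ("body", "TLV", "PGTV", *OAR_STRUCTURES):
        hu[masks[name]] = config.hu_values[name]
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=config.shape)
        hu[masks["body"]] += noise[masks["body"]]
    grid = VolumeGrid(
        np.round(hu).astype(np.int16), grid.spacing, grid.origin
    )

    idx = np.argwhere(masks["PGTV"])
    if idx.size == 0:
        raise ContainmentError("PGTV mask is empty at this resolution")
    isocenter = grid.origin + (idx.mean(axis=0) + 0.5) * grid.spacing
    case = PatientCase(
        config.case_id, grid, StructureSet(masks), isocenter, []
    )
    case.clinical_angles = list(geometric_reference_angles(case).angles)
    return case


def geometric_angle_scores(
    case: PatientCase,
    penalty_weight: float = 1.0,
    step_mm: float = 1.0,
    half_span_mm: float = 600.0,
) -> np.ndarray:
    """Per-degree geometric quality scores (higher is better), length 360.

    For each gantry angle the central ray through the isocenter is
    sampled; the score is minus the water-equivalent path length from
    the body entry to the proximal PGTV edge, minus ``penalty_weight``
    times the total organ-at-risk path length beyond the distal PGTV
    edge (where range overshoot would land).
    """
    grid = case.volume
    oar_union = np.zeros(grid.shape, dtype=np.uint8)
    for name in OAR_STRUCTURES:
        oar_union |= case.structures[name].astype(np.uint8)
    body = case.structures["body"].astype(np.uint8)
    pgtv = case.structures["PGTV"].astype(np.uint8)
    hu = np.asarray(grid.voxels, dtype=np.float32)

    t = np.arange(-half_span_mm, half_span_mm + step_mm / 2, step_mm)
    angles = np.arange(360.0)
    dirs = np.stack([beam_direction(a) for a in angles])  # (360, 3)
    pts = case.isocenter[None, None, :] + t[None, :, None] * dirs[:, None, :]
    coords = grid.mm_to_index(pts.reshape(-1, 3)).T

    hu_s = map_coordinates(
        hu, coords, order=1, mode="constant", cval=float(AIR_HU)
    ).reshape(360, len(t))
    body_s = map_coordinates(
        body, coords, order=0, mode="constant", cval=0
    ).reshape(360, len(t))
    pgtv_s = map_coordinates(
        pgtv, coords, order=0, mode="constant", cval=0
    ).reshape(360, len(t))
    oar_s = map_coordinates(
        oar_union, coords, order=0, mode="constant", cval=0
    ).reshape(360, len(t))

    rel_density = np.clip(1.0 + hu_s / 1000.0, 0.0, None)
    scores = np.full(360, -np.inf)
    for a in range(360):
        p = np.flatnonzero(pgtv_s[a])
        b = np.flatnonzero(body_s[a])
        if p.size == 0 or b.size == 0:
            continue
        entry, prox, dist = b[0], p[0], p[-1]
        wepl = rel_density[a, entry:prox].sum() * step_mm
        oar_beyond = oar_s[a, dist + 1 :].sum() * step_mm
        scores[a] = -wepl - penalty_weight * oar_beyond
    return scores


def geometric_reference_angles(
    case: PatientCase,
    n: int = 3,
    min_sep: float = 30.0,
    penalty_weight: float = 1.0,
):
    """Constrained top-n geometric angles (surrogate for planner picks)."""
    scores = geometric_angle_scores(case, penalty_weight)
    finite = np.isfinite(scores)
    lo = scores[finite].min()
    span = scores[finite].max() - lo
    norm = np.zeros(360)
    if span > 0:
        norm[finite] = (scores[finite] - lo) / span
    return select_angles(SBeam(norm), k=n, min_sep=min_sep)


def toy_dose(case: PatientCase, angles: list[float]) -> DoseGrid:
    """Schematic dose for unit-weight fields (for metric testing only).

    Each field deposits a uniform unit dose in the elliptical cylinder
    swept around the target's BEV cross-section, from the body surface
    up to the distal PGTV edge (plus half a voxel of margin), and
    nothing beyond — a cartoon of a stopping proton field. Fields sum
    with weight one and the total is normalized to a mean PGTV dose of
    100%.
    """
    if len(angles) == 0:
        raise ValueError("at least one beam angle is required")
    grid = case.volume
    axes = [grid.voxel_centers_axis(a) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    rel = pts - case.isocenter
    body = case.structures["body"]
    pgtv = case.structures["PGTV"]
    pgtv_pts = rel[pgtv]
    margin = float(np.max(grid.spacing)) / 2.0

    dose = np.zeros(grid.shape)
    for ang in angles:
        d = beam_direction(ang)
        lateral, up = bev_basis(ang)
        a, b = bev_half_extents(case, ang)
        t = rel @ d
        u = rel @ lateral
        v = rel @ up
        t_dist = float((pgtv_pts @ d).max()) + margin
        cyl = (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0
        fieldmask = body & cyl & (t <= t_dist)
        if not np.any(fieldmask & pgtv):
            raise ValueError(f"field at {ang} deg misses the PGTV")
        dose[fieldmask] += 1.0

    mean_target = dose[pgtv].mean()
    if mean_target <= 0:
        raise ValueError("no dose delivered to the PGTV")
    return DoseGrid(dose * (100.0 / mean_target))


def sample_config(seed: int, case_id: str | None = None) -> PhantomConfig:
    """Draw one phantom from the randomized study family.

    The family varies the tumor position inside the liver (uniform
    direction, 8-22 mm radial offset, +/-8 mm axial) and jitters organ
    centres (+/-4 mm) and sizes (+/-8%), so the geometry-to-angle mapping
    changes smoothly across cases. Draws violating organ containment
    are rejected and redrawn deterministically.
    """
    rng = np.random.default_rng(seed)
    base = PhantomConfig()
    for _ in range(50):
        phi = rng.uniform(0.0, 2 * np.pi)
        r = rng.uniform(8.0, 22.0)
        dz = rng.uniform(-8.0, 8.0)
        offset = (r * np.cos(phi), r * np.sin(phi), dz)
        organs = {}
        for name, ell in DEFAULT_ORGANS.items():
            jc = np.asarray(ell.center) + rng.uniform(-4.0, 4.0, 3)
            js = np.asarray(ell.semi_axes) * rng.uniform(0.92, 1.08, 3)
            if name == "body":
                jc = np.zeros(3)
            organs[name] = Ellipsoid(tuple(jc), tuple(js))
        cfg = replace(
            base,
            organs=organs,
            tumor_offset=offset,
            seed=int(rng.integers(0, 2**31 - 1)),
            case_id=case_id or f"phantom-{seed}",
        )
        try:
            grid = _grid(cfg)
            masks = {
                n: _ellipsoid_mask(grid, e) for n, e in cfg.organs.items()
            }
            tlv_c = np.asarray(cfg.organs["TLV"].center)
            masks["PGTV"] = _ellipsoid_mask(
                grid,
                Ellipsoid(
                    tuple(tlv_c + np.asarray(cfg.tumor_offset)),
                    cfg.tumor_semi_axes,
                ),
            )
            _validate_containment(masks)
        except ContainmentError:
            continue
        return cfg
    raise RuntimeError("could not draw a valid phantom configuration")
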