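"""Constrained beam selection and plan-quality metrics.

The selection rule descends the ranking scores greedily and accepts an
angle only if its circular distance to every already-accepted angle is
at least the minimum separation (30 degrees for three-port plans).
Metrics follow standard DVH practice: a conformity index over the
prescribed isodose volume, V_x (volume fraction at or above a dose
threshold) and per-structure min/mean/max dose statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DoseGrid
from .targets import SBeam, circular_distance


class SelectionInfeasibleError(ValueError):
    """Not enough angles satisfy the separation constraint."""

    def __init__(self, selected: int, requested: int):
        self.selected = selected
        self.requested = requested
        super().__init__(
            f"only {selected} of {requested} angles selectable under the "
            "separation constraint"
        )


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is empty (e.g. no target/isodose overlap)."""


@dataclass
class BeamSet:
    """The selected gantry angles of a plan (three for DS plans)."""

    angles: list[float]
    min_sep: float = 30.0

    def __post_init__(self) -> None:
        self.angles = [float(a) % 360.0 for a in self.angles]
        arr = np.asarray(self.angles)
        for i in range(len(arr)):
            for j in range(i + 1, len(arr)):
                if circular_distance(arr[i], arr[j]) < self.min_sep - 1e-9:
                    raise ValueError(
                        f"angles {arr[i]} and {arr[j]} closer than "
                        f"{self.min_sep} deg"
                    )


def select_angles(
    sbeam: SBeam, k: int = 3, min_sep: float = 30.0
) -> BeamSet:
    """Greedy top-k angle selection under a minimum-separation rule.

    Angles are visited in order of decreasing score (ties broken by the
    lower angle) and accepted iff their circular distance to every
    accepted angle is >= ``min_sep``.
    """
    scores = np.asarray(sbeam.scores)
    order = np.lexsort((np.arange(len(scores)), -scores))
    chosen: list[int] = []
    for idx in order:
        if all(
            circular_distance(float(idx), float(c)) >= min_sep
            for c in chosen
        ):
            chosen.append(int(idx))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise SelectionInfeasibleError(len(chosen), k)
    return BeamSet([float(c) for c in chosen], min_sep)


def conformity_index(
    tv_mask: np.ndarray,
    dose: DoseGrid,
    variant: str = "ratio",
) -> float:
    """Conformity index of the prescribed isodose volume around a target.

    PIV is the set of voxels with dose >= ``dose.prescription_level``.
    The default ``"ratio"`` variant is (TV * PIV) / (TV n PIV)^2, which
    equals 1 for perfect conformity and exceeds 1 when PIV and TV
    mismatch; ``"paddick"`` gives the reciprocal (TV n PIV)^2 / (TV*PIV),
    bounded by 1 from above.
    """
    tv = np.asarray(tv_mask).astype(bool)
    if not tv.any():
        raise ValueError("target mask is empty")
    piv = dose.dose >= dose.prescription_level
    n_tv = int(tv.sum())
    n_piv = int(piv.sum())
    n_ov = int((tv & piv).sum())
    if n_ov == 0 or n_piv == 0:
        raise UndefinedMetricError(
            "target and prescribed isodose volume do not overlap"
        )
    if variant == "ratio":
        return (n_tv * n_piv) / (n_ov**2)
    if variant == "paddick":
        return (n_ov**2) / (n_tv * n_piv)
    raise ValueError(f"unknown CI variant {variant!r}")


def v_xgy(
    dose: DoseGrid, mask: np.ndarray, threshold_pct: float
) -> float:
    """Volume-% of ``mask`` receiving dose >= ``threshold_pct``."""
    m = np.asarray(mask).astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("structure mask is empty")
    return 100.0 * float((dose.dose[m] >= threshold_pct).sum()) / n


def dose_stats(dose: DoseGrid, mask: np.ndarray) -> dict[str, float]:
    """Min/mean/max dose (% of prescription) over a structure."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("structure mask is empty")
    vals = dose.dose[m]
    return {
        "min": float(vals.min()),
        "mean": float(vals.mean()),
        "max": float(vals.max()),
    }


@dataclass
class PlanMetrics:
    """Bundle of plan-quality numbers for one dose distribution."""

    conformity_index: float
    v_xgy: dict[str, dict[float, float]]
    dose_stats: dict[str, dict[str, float]]

    def to_rows(self) -> list[dict[str, object]]:
        """Flatten to one row per structure (for CSV emission)."""
        rows: list[dict[str, object]] = []
        for name, stats in self.dose_stats.items():
            row: dict[str, object] = {"structure": name, **stats}
            for thr, val in self.v_xgy.get(name, {}).items():
                row[f"V{thr:g}%"] = val
            rows.append(row)
        return rows
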