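"""Phase-level dose accumulation on the reference anatomy and the
minimum-margin EUD criterion.

Each fraction's dose is pulled back to the reference frame through its
ground-truth displacement field (trilinear interpolation; out-of-grid
pullbacks contribute zero and are logged) and summed voxel-wise.  Ground
truth fields stand in for a deformable registration; externally supplied
fields with the same layout plug in unchanged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose_metrics import EUDParams, normalized_eud
from .geometry import ctv_series_from_ptv
from .grids import Grid3D, Mask3D

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseResult",
    "pull_back",
    "accumulate_phase",
    "margin_table",
    "min_adequate_margin",
    "NO_ADEQUATE_MARGIN",
]

#: Sentinel returned when no margin up to the largest analyzed one qualifies.
NO_ADEQUATE_MARGIN = "none <= 10"


def pull_back(dose: Grid3D, displacement_mm: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``dose`` at reference-voxel positions displaced by the field.

    ``displacement_mm`` has shape (3, nz, ny, nx): for each reference voxel
    the millimetric offset to its position in the fraction frame.  Trilinear
    by default (``order=1``); ``order=0`` gives the nearest-neighbor oracle
    path.  Samples falling outside the grid contribute zero.
    """
    if displacement_mm.shape != (3, *dose.shape):
        raise ValueError("displacement field shape does not match the dose grid")
    spacing = np.asarray(dose.spacing)
    idx = np.indices(dose.shape, dtype=float)
    coords = idx + displacement_mm / spacing[:, None, None, None]
    out = ndimage.map_coordinates(dose.values, coords.reshape(3, -1),
                                  order=order, mode="constant", cval=0.0)
    n_outside = int(np.any((coords < -0.5)
                           | (coords >= np.array(dose.shape)[:, None, None, None] - 0.5),
                           axis=0).sum())
    if n_outside:
        logger.info("pull_back: %d voxel pullbacks fell outside the grid", n_outside)
    return out.reshape(dose.shape)


def accumulate_phase(fractions: list, plan_type: str = "delivered",
                     order: int = 1) -> Grid3D:
    """Sum the phase's per-fraction doses of ``plan_type`` on the reference frame.

    All fractions must share one grid geometry and carry displacement
    fields.  The result is in Gy; a perfectly delivered course totals
    ``n_fractions * prescription`` (100% of the phase prescription) in the
    target.
    """
    if not fractions:
        raise ValueError("no fractions to accumulate")
    # canonical summation order makes the result independent of list order
    # down to the last bit (floating-point addition does not commute)
    fractions = sorted(fractions, key=lambda fr: str(fr.fraction_id))
    first = fractions[0].dose(plan_type)
    total = np.zeros(first.shape)
    for fr in fractions:
        dose = fr.dose(plan_type)
        if not first.same_lattice(dose):
            raise ValueError("mixed grid geometries within one phase")
        disp = fr.displacement_field()
        if disp is None:
            raise ValueError(f"fraction {fr.fraction_id} has no displacement field")
        total += pull_back(dose, disp, order=order)
    return first.with_values(total)


def margin_table(accumulated: Grid3D, ptv: Mask3D, params: EUDParams,
                 margins_mm: list[float] | None = None) -> dict[float, float | None]:
    """Normalized accumulated EUD of each synthetic CTV_m eroded from the PTV.

    ``params.prescription`` must be the *phase* prescription
    (per-fraction prescription times fraction count).  Margins whose CTV_m
    is empty map to ``None``.
    """
    if margins_mm is None:
        margins_mm = list(range(1, 11))
    series = ctv_series_from_ptv(ptv, margins_mm)
    out: dict[float, float | None] = {}
    any_defined = False
    for m in margins_mm:
        mask = series[f"CTV_{m:g}mm"]
        if mask.is_empty():
            out[m] = None
            continue
        out[m] = normalized_eud(accumulated, mask, params)
        any_defined = True
    if not any_defined:
        raise ValueError("every CTV_m in the series is empty")
    return out


def min_adequate_margin(eud_by_margin: dict[float, float | None],
                        threshold_pct: float = 95.0) -> float | str:
    """Smallest margin whose accumulated EUD strictly exceeds the threshold.

    Scans margins in ascending order; returns :data:`NO_ADEQUATE_MARGIN`
    when none qualifies.
    """
    if not eud_by_margin:
        raise ValueError("empty margin table")
    for m in sorted(eud_by_margin):
        v = eud_by_margin[m]
        if v is not None and v > threshold_pct:
            return m
    return NO_ADEQUATE_MARGIN


@dataclass
class PhaseResult:
    """Accumulated-dose analysis of one treatment phase (>= 3 fractions)."""

    phase_id: str
    n_fractions: int
    accumulated: dict[str, Grid3D]                 # plan type -> reference-frame dose
    eud_by_margin: dict[str, dict[float, float | None]]
    min_margin: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("only phases with >= 3 fractions are analyzed")
        if not self.min_margin:
            self.min_margin = {pt: min_adequate_margin(tab)
                               for pt, tab in self.eud_by_margin.items()}


def analyze_phase(phase_id: str, fractions: list, ptv: Mask3D,
                  tumor_exponent: float, prescription_gy: float,
                  plan_types: tuple[str, ...] = ("scheduled", "adaptive", "delivered"),
                  margins_mm: list[float] | None = None) -> PhaseResult:
    """Accumulate one phase for each plan type and build its margin table.

    Scheduled and adaptive courses are both computed counterfactually over
    all fractions of the phase; the 'delivered' course follows each
    fraction's delivered flag.
    """
    n = len(fractions)
    if n < 3:
        raise ValueError("only phases with >= 3 fractions are analyzed")
    params = EUDParams(a=tumor_exponent, prescription=n * prescription_gy)
    accumulated = {pt: accumulate_phase(fractions, pt) for pt in plan_types}
    tables = {pt: margin_table(acc, ptv, params, margins_mm)
              for pt, acc in accumulated.items()}
    return PhaseResult(phase_id=phase_id, n_fractions=n,
                       accumulated=accumulated, eud_by_margin=tables)


def margin_summary(results: list[PhaseResult], plan_types=("adaptive", "scheduled"),
                   margins_mm: list[float] | None = None):
    """Cross-phase min/max/mean/median table of accumulated EUD per margin."""
    import pandas as pd

    if margins_mm is None:
        margins_mm = list(range(1, 11))
    rows = []
    for m in margins_mm:
        row: dict[str, float | str] = {"margin_mm": m}
        for pt in plan_types:
            vals = [r.eud_by_margin[pt][m] for r in results
                    if r.eud_by_margin[pt].get(m) is not None]
            arr = np.array(vals, dtype=float)
            row[f"{pt}_min"] = arr.min() if arr.size else np.nan
            row[f"{pt}_max"] = arr.max() if arr.size else np.nan
            row[f"{pt}_mean"] = arr.mean() if arr.size else np.nan
            row[f"{pt}_median"] = float(np.median(arr)) if arr.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
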