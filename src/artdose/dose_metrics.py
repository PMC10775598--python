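"""Generalized equivalent uniform dose (gEUD) and DVH metric panel.

The gEUD of a structure is the power mean ``(sum_i v_i d_i**a) ** (1/a)``
over its voxel doses, with equal per-voxel volume weights.  Negative
exponents make it sensitive to cold spots (``a = -20`` for tumors); ``a = 1``
is the mean dose; large positive exponents approach the maximum (serial
organs, e.g. ``a = 9.1`` for larynx).

All computations use the raw voxel doses, never a binned DVH; a binned path
(:func:`geud_from_dvh`) exists only for cross-checking, because binning
biases minimum-sensitive exponents.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .grids import Grid3D, Mask3D

__all__ = [
    "EUDParams",
    "MetricRow",
    "DEFAULT_EXPONENTS",
    "geud",
    "geud_from_doses",
    "geud_from_dvh",
    "normalized_eud",
    "dvh",
    "d_at_volume",
    "v_at_dose",
    "metric_row",
]

#: Default tissue exponent registry.  Tumor exponent is strongly
#: minimum-sensitive; parotid is near-parallel; larynx is serial-type.
DEFAULT_EXPONENTS: dict[str, float] = {
    "tumor": -20.0,
    "parotid": 1.43,
    "larynx": 9.1,
}

#: Fraction of prescription used to floor voxel doses before a negative-power
#: sum (d**a diverges at zero dose).
ZERO_DOSE_GUARD_FRACTION = 1e-3


@dataclass(frozen=True)
class EUDParams:
    """Tissue exponent and prescription for normalized EUD reporting."""

    a: float
    prescription: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("invalid exponent: a must be non-zero")
        if not self.prescription > 0:
            raise ValueError("prescription must be positive")


@dataclass(frozen=True)
class MetricRow:
    """Per fraction x structure x plan-type dose summary (percent of prescription)."""

    fraction_id: str
    structure: str
    plan_type: str  # one of {reference, scheduled, adaptive}
    eud_pct: float
    v100_pct: float
    d99_pct: float
    d95_pct: float
    d90_pct: float
    dmin_pct: float
    dmax_pct: float
    n_floored_voxels: int = 0

    @property
    def homogeneity_pct(self) -> float:
        return self.dmax_pct - self.d99_pct

    def __post_init__(self) -> None:
        chain = (self.dmin_pct, self.d99_pct, self.d95_pct, self.d90_pct, self.dmax_pct)
        if not all(x <= y + 1e-9 for x, y in zip(chain, chain[1:])):
            raise ValueError("D-metric ordering violated: "
                             f"Dmin<=D99<=D95<=D90<=Dmax required, got {chain}")
        if not -1e-9 <= self.v100_pct <= 100 + 1e-9:
            raise ValueError("v100_pct must lie in [0, 100]")


def _masked_doses(dose: Grid3D, mask: Mask3D) -> np.ndarray:
    if dose.shape != mask.shape:
        raise ValueError("dose and mask shapes differ")
    if mask.is_empty():
        raise ValueError("empty structure")
    return dose.values[mask.flags]


def geud_from_doses(doses: np.ndarray, a: float, floor: float | None = None) -> tuple[float, int]:
    """gEUD of a flat dose sample; returns (value, number of floored voxels).

    Evaluated in log space so that exponents like +/-100 neither overflow
    nor lose the min/max limit behavior.
    """
    if a == 0:
        raise ValueError("invalid exponent: a must be non-zero")
    d = np.asarray(doses, dtype=float)
    if d.size == 0:
        raise ValueError("empty structure")
    n_floored = 0
    if a < 0:
        bad = d <= 0 if floor is None else d < floor
        n_floored = int(bad.sum())
        if n_floored:
            if floor is None:
                raise ValueError("non-positive dose with negative exponent and no guard")
            d = np.maximum(d, floor)
    positive = d > 0
    if not positive.any():
        return 0.0, n_floored  # a > 0, all-zero dose
    # sum v_i d_i^a = (1/n) sum d_i^a; zero doses contribute nothing for a > 0
    log_terms = a * np.log(d[positive])
    log_power_sum = logsumexp(log_terms) - np.log(d.size)
    return float(np.exp(log_power_sum / a)), n_floored


def geud(dose: Grid3D, mask: Mask3D, a: float, floor: float | None = None) -> float:
    """gEUD (Gy) of ``dose`` restricted to ``mask`` with tissue exponent ``a``."""
    value, _ = geud_from_doses(_masked_doses(dose, mask), a, floor=floor)
    return value


def normalized_eud(dose: Grid3D, mask: Mask3D, params: EUDParams) -> float:
    """gEUD as percent of prescription, with the zero-dose guard applied.

    For negative exponents, voxel doses are floored at
    ``ZERO_DOSE_GUARD_FRACTION * prescription`` before the power sum.
    """
    floor = ZERO_DOSE_GUARD_FRACTION * params.prescription if params.a < 0 else None
    value, _ = geud_from_doses(_masked_doses(dose, mask), params.a, floor=floor)
    return 100.0 * value / params.prescription


def dvh(dose: Grid3D, mask: Mask3D, bin_width: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: (bin edges in Gy, volume fraction receiving >= edge).

    Edge 0 always carries fraction 1; the curve is non-increasing; the last
    edge exceeds the maximum masked dose.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = _masked_doses(dose, mask)
    n_bins = int(np.ceil(d.max() / bin_width)) + 1 if d.max() > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    fraction = (d[None, :] >= edges[:, None]).mean(axis=1)
    fraction[0] = 1.0  # doses are non-negative by Grid3D invariant
    return edges, fraction


def geud_from_dvh(dose: Grid3D, mask: Mask3D, a: float, bin_width: float = 0.01,
                  floor: float | None = None) -> float:
    """Cross-check path: gEUD from a differential DVH at ``bin_width`` Gy."""
    d = _masked_doses(dose, mask)
    if a < 0:
        if floor is not None:
            d = np.maximum(d, floor)
        elif (d <= 0).any():
            raise ValueError("non-positive dose with negative exponent and no guard")
    edges = np.arange(int(np.ceil(d.max() / bin_width)) + 2) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = counts / counts.sum()
    nz = weights > 0
    if a < 0:
        centers = np.maximum(centers, bin_width / 2)
    log_terms = a * np.log(centers[nz]) + np.log(weights[nz])
    return float(np.exp(logsumexp(log_terms) / a))


def d_at_volume(dose: Grid3D, mask: Mask3D, q: float) -> float:
    """D_q: the largest dose (Gy) received by at least fraction ``q`` of the structure.

    Order statistic at index ``ceil(q * n)`` of the descending-sorted voxel
    doses, without interpolation.  ``q = 1`` is the minimum dose; ``q -> 0+``
    approaches the maximum.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    d = np.sort(_masked_doses(dose, mask))[::-1]
    k = int(np.ceil(q * d.size))
    return float(d[k - 1])


def v_at_dose(dose: Grid3D, mask: Mask3D, threshold_pct: float, prescription: float) -> float:
    """V_t: percent of structure volume receiving at least ``threshold_pct`` of prescription."""
    if not prescription > 0:
        raise ValueError("prescription must be positive")
    d = _masked_doses(dose, mask)
    threshold = threshold_pct / 100.0 * prescription
    return float(100.0 * (d >= threshold).mean())


def metric_row(dose: Grid3D, mask: Mask3D, params: EUDParams,
               fraction_id: str = "", plan_type: str = "reference") -> MetricRow:
    """Bundle the full endpoint metric panel for one dose/structure pair."""
    d = _masked_doses(dose, mask)
    floor = ZERO_DOSE_GUARD_FRACTION * params.prescription if params.a < 0 else None
    eud, n_floored = geud_from_doses(d, params.a, floor=floor)
    p = params.prescription
    to_pct = lambda x: 100.0 * x / p  # noqa: E731
    return MetricRow(
        fraction_id=fraction_id,
        structure=mask.name,
        plan_type=plan_type,
        eud_pct=to_pct(eud),
        v100_pct=v_at_dose(dose, mask, 100.0, p),
        d99_pct=to_pct(d_at_volume(dose, mask, 0.99)),
        d95_pct=to_pct(d_at_volume(dose, mask, 0.95)),
        d90_pct=to_pct(d_at_volume(dose, mask, 0.90)),
        dmin_pct=to_pct(float(d.min())),
        dmax_pct=to_pct(float(d.max())),
        n_floored_voxels=n_floored,
    )
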