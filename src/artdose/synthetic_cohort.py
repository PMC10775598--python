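"""Synthetic phantom cohort: anatomy, motion, idealized dose shaping, selection.

The cohort stands in for clinical per-fraction data.  A mobile target
compartment (the "tongue" CTV) translates between planning anatomy and each
fraction (interfractional shift) and again between the pre- and
post-adaptation snapshots (intrafractional shift).  Shift components are
heavy-tailed (scaled Student-t) so occasional >10 mm excursions occur; eight
scalar landmark readouts are calibrated linear projections of the shift
vectors.  Doses come from an idealized shaper (Gaussian-smoothed PTV
indicator normalized at the target surface) rather than a treatment planning
optimizer; the displacement field is a rigid translation of the compartment
blended to zero with a cosine taper, giving invertible ground truth for
dose accumulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.signal import fftconvolve
from scipy.stats import norm, t as student_t

from .config import (GridConfig, MotionConfig, PlanConfig, PolicyConfig,
                     RunConfig, LANDMARK_LABELS)
from .dose_metrics import EUDParams, MetricRow, metric_row, normalized_eud
from .geometry import expand
from .grids import Grid3D, Mask3D, StructureRole, StructureSet

__all__ = [
    "AnatomyPhantom",
    "ShiftSample",
    "FractionRecord",
    "MotionModel",
    "Planner",
    "WarpModel",
    "Cohort",
    "build_phantom",
    "sample_shifts",
    "make_scheduled_dose",
    "make_adaptive_dose",
    "select_delivered",
    "generate_cohort",
    "shift_mask",
]

AXES = ("z", "y", "x")


# --------------------------------------------------------------------------
# Phantom anatomy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyPhantom:
    """Reference (planning) anatomy on a fixed lattice."""

    grid: GridConfig
    structures: StructureSet

    @property
    def body(self) -> Mask3D:
        return self.structures["BODY"]

    @property
    def ctv(self) -> Mask3D:
        return self.structures["CTV"]

    @property
    def ptv(self) -> Mask3D:
        return self.structures["PTV"]

    def oars(self) -> list[Mask3D]:
        return self.structures.by_role(StructureRole.OAR)


def _ellipsoid(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    cz, cy, cx = center_mm
    az, ay, ax = semi_axes_mm
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


#: Default structure layout (center offsets from the grid center and
#: semi-axes, all mm).  The CTV is the mobile "tongue" compartment.
DEFAULT_SHAPES = {
    "BODY": {"offset": (0, 0, 0), "semi_axes": (60, 55, 55)},
    "CTV": {"offset": (0, 0, 0), "semi_axes": (14, 12, 12)},
    "parotid_l": {"offset": (0, 0, -38), "semi_axes": (12, 8, 8)},
    "parotid_r": {"offset": (0, 0, 38), "semi_axes": (12, 8, 8)},
    "larynx": {"offset": (30, 7, 0), "semi_axes": (10, 8, 8)},
    "spinal_cord": {"offset": (0, 40, 0), "semi_axes": (999, 5, 5)},
}

OAR_NAMES = ("parotid_l", "parotid_r", "larynx", "spinal_cord")


def build_phantom(grid: GridConfig | None = None, plan: PlanConfig | None = None,
                  shapes: dict | None = None, seed: int | None = None) -> AnatomyPhantom:
    """Build the reference anatomy.  Deterministic given (config, seed).

    ``seed`` is accepted for interface symmetry; the default phantom is a
    fixed parametric shape set and draws nothing.
    """
    grid = grid or GridConfig()
    plan = plan or PlanConfig()
    shapes = shapes or DEFAULT_SHAPES
    shape, spacing = grid.shape, grid.spacing_mm
    center = tuple((n - 1) * s / 2 for n, s in zip(shape, spacing))

    def mk(name, role):
        spec = shapes[name]
        c = tuple(c0 + o for c0, o in zip(center, spec["offset"]))
        flags = _ellipsoid(shape, spacing, c, spec["semi_axes"])
        return Mask3D(flags, name=name, role=role, spacing=spacing)

    ss = StructureSet()
    body = mk("BODY", StructureRole.BODY)
    ctv = mk("CTV", StructureRole.CTV)
    ptv = expand(ctv, plan.planning_margin_mm).with_flags(
        expand(ctv, plan.planning_margin_mm).flags, name="PTV", role=StructureRole.PTV)
    ss.add(body)
    ss.add(ctv)
    ss.add(ptv)
    for name in OAR_NAMES:
        if name in shapes:
            oar = mk(name, StructureRole.OAR)
            # structures are clipped to the BODY contour (the cord cylinder
            # intentionally spans the whole grid before clipping)
            oar = oar.with_flags(oar.flags & body.flags)
            if (oar.flags & ctv.flags).any():
                raise ValueError(f"config error: OAR '{name}' overlaps the CTV")
            ss.add(oar)
    if not (ctv.flags <= ptv.flags).all() or not (ptv.flags <= body.flags).all():
        raise ValueError("containment violated: CTV within PTV within BODY required")
    for oar in ss.by_role(StructureRole.OAR):
        if not (oar.flags <= body.flags).all():
            raise ValueError(f"OAR '{oar.name}' extends outside BODY")
    return AnatomyPhantom(grid=grid, structures=ss)


# --------------------------------------------------------------------------
# Motion model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftSample:
    """One fraction's motion: compartment shift vectors plus landmark readouts."""

    inter: np.ndarray           # (3,) mm, planning CT -> CBCT1
    intra: np.ndarray           # (3,) mm, CBCT1 -> CBCT2
    landmark_inter: np.ndarray  # (8,) signed mm
    landmark_intra: np.ndarray  # (8,) signed mm

    def __post_init__(self) -> None:
        for name in ("inter", "intra"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        for name in ("landmark_inter", "landmark_intra"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (8,):
                raise ValueError(f"{name} must have exactly 8 entries")
            object.__setattr__(self, name, v)

    @property
    def total(self) -> np.ndarray:
        return self.inter + self.intra


class MotionModel:
    """Heavy-tailed shift sampler with numerically calibrated landmark gains.

    Landmark ``k`` reads ``gain_k * shift[axis_k] + noise``; the gain is
    solved so that the model's own numerically integrated 95th percentile of
    the absolute readout hits the configured per-parameter target.  The
    intrafractional shift couples to the interfractional one through ``rho``,
    which induces the positive |inter| vs |intra| correlation seen clinically.
    """

    _GRID_HALF_MM = 160.0
    _GRID_STEP_MM = 0.02

    def __init__(self, config: MotionConfig | None = None) -> None:
        self.config = config or MotionConfig()
        c = self.config
        self._xs = np.arange(-self._GRID_HALF_MM, self._GRID_HALF_MM + 1e-9,
                             self._GRID_STEP_MM)
        self._inter_gains = np.array([
            self._solve_gain(c.inter_p95_targets_mm[k], self._inter_component_pdf())
            for k in range(8)
        ])
        self._intra_gains = np.array([
            self._solve_gain(c.intra_p95_targets_mm[k], self._intra_component_pdf())
            for k in range(8)
        ])

    # ---- numeric distribution machinery -----------------------------------

    def _scaled_t_pdf(self, scale: float) -> np.ndarray:
        return student_t.pdf(self._xs / scale, self.config.df) / scale

    def _inter_component_pdf(self) -> np.ndarray:
        return self._scaled_t_pdf(self.config.inter_scale_mm)

    def _intra_component_pdf(self) -> np.ndarray:
        """Density of rho * inter_component + independent t noise."""
        c = self.config
        if c.rho == 0:
            return self._scaled_t_pdf(c.intra_scale_mm)
        coupled = self._scaled_t_pdf(c.rho * c.inter_scale_mm)
        noise = self._scaled_t_pdf(c.intra_scale_mm)
        dens = fftconvolve(coupled, noise, mode="same") * self._GRID_STEP_MM
        return dens

    def abs_readout_quantile(self, gain: float, component_pdf: np.ndarray,
                             q: float = 0.95) -> float:
        """Quantile of |gain * S + eps|, eps ~ N(0, landmark_noise).

        Numerically integrated: the readout density is the rescaled
        component density convolved with the Gaussian noise density.
        """
        dx = self._GRID_STEP_MM
        xs = self._xs
        scaled = np.interp(xs / gain, xs, component_pdf, left=0.0, right=0.0) / gain
        sd = self.config.landmark_noise_mm
        half = int(np.ceil(6 * sd / dx))
        kern = norm.pdf(np.arange(-half, half + 1) * dx, scale=sd)
        dens = fftconvolve(scaled, kern * dx, mode="same")
        cdf = np.cumsum(dens) * dx
        cdf /= cdf[-1]
        ys = xs[xs >= 0]
        abs_cdf = np.interp(ys, xs, cdf) - np.interp(-ys, xs, cdf)
        return float(np.interp(q, abs_cdf, ys))

    def _solve_gain(self, target_mm: float, component_pdf: np.ndarray) -> float:
        f = lambda g: self.abs_readout_quantile(g, component_pdf) - target_mm  # noqa: E731
        return float(brentq(f, 1e-3, 50.0, xtol=1e-6))

    # ---- public calibration queries ---------------------------------------

    def expected_inter_p95(self, k: int) -> float:
        """Model 95th percentile of |landmark_inter[k]| (equals the target)."""
        return self.abs_readout_quantile(self._inter_gains[k],
                                         self._inter_component_pdf())

    def expected_intra_p95(self, k: int) -> float:
        return self.abs_readout_quantile(self._intra_gains[k],
                                         self._intra_component_pdf())

    # ---- sampling ---------------------------------------------------------

    def sample(self, n_fractions: int, rng: np.random.Generator) -> list[ShiftSample]:
        c = self.config
        out = []
        for _ in range(n_fractions):
            inter = c.inter_scale_mm * rng.standard_t(c.df, size=3)
            intra = c.rho * inter + c.intra_scale_mm * rng.standard_t(c.df, size=3)
            axes = np.asarray(c.landmark_axes)
            lm_inter = (self._inter_gains * inter[axes]
                        + rng.normal(0.0, c.landmark_noise_mm, size=8))
            lm_intra = (self._intra_gains * intra[axes]
                        + rng.normal(0.0, c.landmark_noise_mm, size=8))
            out.append(ShiftSample(inter=inter, intra=intra,
                                   landmark_inter=lm_inter, landmark_intra=lm_intra))
        return out


def sample_shifts(n_fractions: int, motion_config: MotionConfig | None = None,
                  seed: int = 0) -> list[ShiftSample]:
    """Draw ``n_fractions`` shift samples; deterministic given (config, seed)."""
    model = MotionModel(motion_config)
    return model.sample(n_fractions, np.random.default_rng(seed))


# --------------------------------------------------------------------------
# Displacement field
# --------------------------------------------------------------------------

class WarpModel:
    """Rigid compartment translation blended to zero with a cosine taper.

    The scalar weight is 1 inside the CTV and falls as
    ``0.5 (1 + cos(pi d / taper))`` over ``taper`` mm outside it, so the
    displacement field is zero outside the compartment's influence region.
    """

    def __init__(self, ctv: Mask3D, taper_mm: float = 10.0) -> None:
        dist = ndimage.distance_transform_edt(~ctv.flags, sampling=ctv.spacing)
        w = np.zeros_like(dist)
        inside = dist <= 0
        band = (dist > 0) & (dist < taper_mm)
        w[inside] = 1.0
        w[band] = 0.5 * (1.0 + np.cos(np.pi * dist[band] / taper_mm))
        self.weight = w
        self.spacing = ctv.spacing

    def field(self, shift_mm: np.ndarray) -> np.ndarray:
        """Displacement field (3, nz, ny, nx) in mm: reference voxel -> day position."""
        shift_mm = np.asarray(shift_mm, dtype=float)
        return shift_mm[:, None, None, None] * self.weight[None]


def shift_mask(mask: Mask3D, shift_mm: np.ndarray, name: str | None = None) -> Mask3D:
    """Translate a mask by a (possibly sub-voxel) millimetric shift."""
    shift_vox = np.asarray(shift_mm, dtype=float) / np.asarray(mask.spacing)
    moved = ndimage.shift(mask.flags.astype(float), shift_vox, order=1,
                          mode="constant", cval=0.0)
    return mask.with_flags(moved > 0.5, name=name)


# --------------------------------------------------------------------------
# Idealized planner
# --------------------------------------------------------------------------

class Planner:
    """Dose shaper standing in for the treatment planning optimizer.

    The dose is the Gaussian-smoothed target indicator normalized so the
    flat target surface receives exactly the prescription (smoothed value
    0.5), capped at ``hotspot_cap`` times prescription.  The full target
    therefore sits at or above prescription with a penumbra of width
    ``sigma_penumbra`` falling off outside — the minimum-sensitive EUD
    behavior the analysis probes, without an optimizer in the loop.
    """

    def __init__(self, phantom: AnatomyPhantom, plan: PlanConfig) -> None:
        self.phantom = phantom
        self.plan = plan
        self._reference: Grid3D | None = None

    def shape_dose(self, target: Mask3D) -> Grid3D:
        p = self.plan
        sigma_vox = [p.sigma_penumbra_mm / s for s in target.spacing]
        g = ndimage.gaussian_filter(target.flags.astype(float), sigma=sigma_vox)
        dose = p.prescription_gy * np.minimum(g / 0.5, p.hotspot_cap)
        return Grid3D(dose, spacing=target.spacing)

    def reference_dose(self) -> Grid3D:
        if self._reference is None:
            self._reference = self.shape_dose(self.phantom.ptv)
        return self._reference

    def adaptive_dose(self, day_ctv: Mask3D) -> Grid3D:
        day_ptv = expand(day_ctv, self.plan.adaptive_margin_mm)
        return self.shape_dose(day_ptv)


def _check_in_body(day_ctv: Mask3D, body: Mask3D, ref_n_voxels: int) -> None:
    # voxels falling off the grid vanish from the shifted mask, so volume
    # loss is part of the containment check; resampling alone moves the
    # count by a few percent at most
    if day_ctv.n_voxels < 0.9 * ref_n_voxels \
            or not (day_ctv.flags <= body.flags).all():
        raise ValueError("shift moves the CTV outside the BODY contour")


def make_scheduled_dose(phantom: AnatomyPhantom, planner: Planner,
                        shift: ShiftSample) -> Grid3D:
    """Scheduled plan: the room-fixed reference dose, unchanged by the shift.

    The anatomy of the day moves under it; callers evaluate metrics against
    the shifted CTV.  Raises if the shift carries the CTV outside BODY.
    """
    day_ctv = shift_mask(phantom.ctv, shift.inter)
    _check_in_body(day_ctv, phantom.body, phantom.ctv.n_voxels)
    return planner.reference_dose()


def make_adaptive_dose(phantom: AnatomyPhantom, planner: Planner,
                       shift: ShiftSample) -> Grid3D:
    """Adaptive plan: the dose shaper applied to the day's PTV.

    The day PTV is the interfraction-shifted CTV expanded by the adaptive
    margin; the residual intrafraction shift is *not* part of this dose — it
    degrades delivery and enters through the delivered-anatomy evaluation.
    """
    day_ctv = shift_mask(phantom.ctv, shift.inter)
    _check_in_body(day_ctv, phantom.body, phantom.ctv.n_voxels)
    return planner.adaptive_dose(day_ctv)


# --------------------------------------------------------------------------
# Plan selection
# --------------------------------------------------------------------------

def select_delivered(ctv_scheduled: MetricRow, ctv_adaptive: MetricRow,
                     oar_scheduled: dict[str, float] | None = None,
                     oar_adaptive: dict[str, float] | None = None,
                     policy: PolicyConfig | None = None) -> str:
    """Pick the delivered plan label ('scheduled' or 'adaptive').

    Adaptive is delivered iff its CTV EUD exceeds the scheduled one by more
    than ``policy.threshold_pct`` and no OAR EUD worsens by more than
    ``policy.oar_tolerance_pct``; ties go to the scheduled plan.
    """
    policy = policy or PolicyConfig()
    gain = ctv_adaptive.eud_pct - ctv_scheduled.eud_pct
    if gain <= policy.threshold_pct:
        return "scheduled"
    oar_scheduled = oar_scheduled or {}
    oar_adaptive = oar_adaptive or {}
    for name, sched_eud in oar_scheduled.items():
        if name in oar_adaptive:
            if oar_adaptive[name] - sched_eud > policy.oar_tolerance_pct:
                return "scheduled"
    return "adaptive"


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

@dataclass
class FractionRecord:
    """One treatment fraction of the synthetic cohort."""

    patient_id: str
    phase_id: str
    fraction_id: str
    shift: ShiftSample
    scheduled_dose: Grid3D
    adaptive_dose: Grid3D
    delivered: str                      # 'scheduled' or 'adaptive'
    warp: WarpModel = field(repr=False)
    course: str = "boost"

    def displacement_field(self) -> np.ndarray:
        """Ground-truth field for the delivered (CBCT2) anatomy, mm."""
        return self.warp.field(self.shift.total)

    def dose(self, plan_type: str) -> Grid3D:
        if plan_type == "scheduled":
            return self.scheduled_dose
        if plan_type == "adaptive":
            return self.adaptive_dose
        if plan_type == "delivered":
            return self.dose(self.delivered)
        raise ValueError(f"unknown plan type {plan_type!r}")


@dataclass
class Cohort:
    config: RunConfig
    phantom: AnatomyPhantom
    planner: Planner
    fractions: list[FractionRecord]

    def phases(self) -> dict[str, list[FractionRecord]]:
        out: dict[str, list[FractionRecord]] = {}
        for fr in self.fractions:
            out.setdefault(fr.phase_id, []).append(fr)
        return out


def generate_cohort(config: RunConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate the full synthetic cohort deterministically.

    One ``SeedSequence`` child per patient keeps draws independent of cohort
    ordering.  Plan selection runs the default policy on CBCT1 metrics for
    the CTV and OARs.
    """
    config = config or RunConfig()
    master = config.master_seed if seed is None else seed
    phantom = build_phantom(config.grid, config.plan)
    planner = Planner(phantom, config.plan)
    motion = MotionModel(config.motion)
    warp = WarpModel(phantom.ctv, taper_mm=config.motion.taper_mm)
    params_ctv = EUDParams(a=config.exponents["tumor"],
                           prescription=config.plan.prescription_gy)

    oar_params = {}
    for oar in phantom.oars():
        key = "parotid" if oar.name.startswith("parotid") else oar.name
        if key not in config.exponents:
            raise KeyError(
                f"no tissue exponent configured for OAR '{oar.name}'; "
                "add it to the exponents registry")
        oar_params[oar.name] = EUDParams(a=config.exponents[key],
                                         prescription=config.plan.prescription_gy)

    seeds = np.random.SeedSequence(master).spawn(config.cohort.n_patients)
    fractions: list[FractionRecord] = []
    pattern = config.cohort.fraction_pattern
    phase_counter = 0
    for p_idx in range(config.cohort.n_patients):
        rng = np.random.default_rng(seeds[p_idx])
        patient_id = f"P{p_idx + 1:02d}"
        for _ in range(config.cohort.phases_per_patient):
            n_frac = pattern[phase_counter % len(pattern)]
            phase_id = f"{patient_id}_phase1" if config.cohort.phases_per_patient == 1 \
                else f"{patient_id}_phase{phase_counter + 1}"
            course = "boost" if p_idx % 10 < 7 else "initial"
            shifts = motion.sample(n_frac, rng)
            for f_idx, shift in enumerate(shifts):
                sched = make_scheduled_dose(phantom, planner, shift)
                adapt = make_adaptive_dose(phantom, planner, shift)
                day_ctv = shift_mask(phantom.ctv, shift.inter)
                row_s = metric_row(sched, day_ctv, params_ctv, plan_type="scheduled")
                row_a = metric_row(adapt, day_ctv, params_ctv, plan_type="adaptive")
                oar_s = {o.name: normalized_eud(sched, o, oar_params[o.name])
                         for o in phantom.oars()}
                oar_a = {o.name: normalized_eud(adapt, o, oar_params[o.name])
                         for o in phantom.oars()}
                delivered = select_delivered(row_s, row_a, oar_s, oar_a,
                                             config.policy)
                fractions.append(FractionRecord(
                    patient_id=patient_id,
                    phase_id=phase_id,
                    fraction_id=f"{phase_id}_f{f_idx + 1}",
                    shift=shift,
                    scheduled_dose=sched,
                    adaptive_dose=adapt,
                    delivered=delivered,
                    warp=warp,
                    course=course,
                ))
            phase_counter += 1
    return Cohort(config=config, phantom=phantom, planner=planner,
                  fractions=fractions)


def deviation_table(cohort: Cohort):
    """Long-format landmark deviation table (fraction x parameter rows)."""
    import pandas as pd

    rows = []
    for fr in cohort.fractions:
        for k in range(8):
            rows.append({
                "patient_id": fr.patient_id,
                "phase_id": fr.phase_id,
                "fraction_id": fr.fraction_id,
                "parameter": k + 1,
                "label": LANDMARK_LABELS[k],
                "inter_mm": fr.shift.landmark_inter[k],
                "intra_mm": fr.shift.landmark_intra[k],
            })
    return pd.DataFrame(rows)
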