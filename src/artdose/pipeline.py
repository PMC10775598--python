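"""End-to-end orchestration: cohort generation, per-fraction metrics, plan
selection, accumulation/margin analysis, motion statistics, and report
artifacts.  Re-running with the same config and seed reproduces every
output bit-identically.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .accumulation import analyze_phase, margin_summary
from .config import RunConfig, save_config
from .dose_metrics import EUDParams, metric_row
from .landmark_stats import (correlations, delta_abs, ecdf, percentile_summary,
                             percentile_with_ci, scale_test, signed_rank_test)
from .synthetic_cohort import (Cohort, deviation_table, generate_cohort,
                               shift_mask)

logger = logging.getLogger(__name__)

__all__ = [
    "run_cohort",
    "summarize_cohort",
    "fixture_manifest",
    "table1_fixture",
    "build_manifest",
    "fraction_metrics",
    "validate_report",
]

METRIC_COLUMNS = [
    "fraction_id", "patient_id", "phase_id", "structure", "plan_type",
    "eud_pct", "v100_pct", "d99_pct", "d95_pct", "d90_pct",
    "dmin_pct", "dmax_pct", "homogeneity_pct", "n_floored_voxels",
]


# --------------------------------------------------------------------------
# Per-fraction metrics
# --------------------------------------------------------------------------

def fraction_metrics(cohort: Cohort) -> pd.DataFrame:
    """CTV and OAR metric panel for every fraction and both plan types.

    CTV metrics are evaluated on the CBCT1 (interfraction-shifted) anatomy —
    the snapshot on which the plan decision is made; OARs are static.
    """
    cfg = cohort.config
    params_ctv = EUDParams(a=cfg.exponents["tumor"],
                           prescription=cfg.plan.prescription_gy)
    rows = []
    for fr in cohort.fractions:
        day_ctv = shift_mask(cohort.phantom.ctv, fr.shift.inter, name="CTV")
        for plan_type in ("scheduled", "adaptive"):
            mr = metric_row(fr.dose(plan_type), day_ctv, params_ctv,
                            fraction_id=fr.fraction_id, plan_type=plan_type)
            rows.append({**mr.__dict__, "homogeneity_pct": mr.homogeneity_pct,
                         "patient_id": fr.patient_id, "phase_id": fr.phase_id})
            for oar in cohort.phantom.oars():
                key = "parotid" if oar.name.startswith("parotid") else oar.name
                if key not in cfg.exponents:
                    raise KeyError(f"no tissue exponent configured for '{oar.name}'")
                p = EUDParams(a=cfg.exponents[key],
                              prescription=cfg.plan.prescription_gy)
                omr = metric_row(fr.dose(plan_type), oar, p,
                                 fraction_id=fr.fraction_id, plan_type=plan_type)
                rows.append({**omr.__dict__, "homogeneity_pct": omr.homogeneity_pct,
                             "patient_id": fr.patient_id, "phase_id": fr.phase_id})
    return pd.DataFrame(rows)[METRIC_COLUMNS]


def build_manifest(cohort: Cohort) -> pd.DataFrame:
    rows = [{
        "patient_id": fr.patient_id,
        "phase_id": fr.phase_id,
        "fraction_id": fr.fraction_id,
        "mode": "adaptive",
        "course": fr.course,
        "delivered": fr.delivered,
    } for fr in cohort.fractions]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort summary arithmetic
# --------------------------------------------------------------------------

def _pct(num: int, den: int) -> float | None:
    if den == 0:
        logger.warning("zero denominator in cohort summary")
        return None
    return round(100.0 * num / den, 1)


def summarize_cohort(manifest: pd.DataFrame) -> dict:
    """Cohort-level counts and percentages from a fraction manifest.

    The manifest has one row per fraction (IGRT-only patients may appear as
    single ``mode='igrt'`` rows).  Percentages are rounded to one decimal;
    zero denominators yield nulls with a logged warning.
    """
    required = {"patient_id", "mode"}
    if manifest.empty or not required <= set(manifest.columns):
        logger.warning("empty or incomplete manifest")
        return {"n_patients": 0, "n_art_patients": 0, "pct_art": None,
                "n_adaptive_fractions": 0, "n_applied_adaptive": 0,
                "pct_applied": None, "pct_boost_course": None}
    n_patients = manifest["patient_id"].nunique()
    adaptive = manifest[manifest["mode"] == "adaptive"]
    art_patients = adaptive["patient_id"].unique()
    n_art = len(art_patients)
    n_adaptive_fractions = len(adaptive)
    delivered = adaptive.get("delivered")
    n_applied = int((delivered == "adaptive").sum()) if delivered is not None else 0
    boost = initial = 0
    if "course" in adaptive.columns:
        per_patient = adaptive.groupby("patient_id")["course"].first()
        boost = int((per_patient == "boost").sum())
        initial = int((per_patient == "initial").sum())
    return {
        "n_patients": int(n_patients),
        "n_art_patients": int(n_art),
        "pct_art": _pct(n_art, n_patients),
        "n_adaptive_fractions": int(n_adaptive_fractions),
        "n_applied_adaptive": n_applied,
        "pct_applied": _pct(n_applied, n_adaptive_fractions),
        "pct_boost_course": _pct(boost, boost + initial),
    }


def table1_fixture() -> pd.DataFrame:
    """Per-site patient counts of the published cohort characteristics table."""
    rows = [
        # (treatment, site, igrt_only, art_boost, art_initial)
        ("definitive", "oropharyngeal", 12, 1, 0),
        ("definitive", "oral_cavity", 13, 1, 0),
        ("definitive", "hypopharyngeal", 0, 0, 0),
        ("definitive", "larynx", 2, 0, 0),
        ("definitive", "cup_syndrome", 0, 0, 0),
        ("definitive", "other", 1, 0, 0),
        ("postoperative", "oropharyngeal", 10, 4, 2),
        ("postoperative", "oral_cavity", 7, 1, 1),
        ("postoperative", "hypopharyngeal", 1, 0, 0),
        ("postoperative", "larynx", 1, 0, 0),
        ("postoperative", "cup_syndrome", 0, 0, 0),
        ("postoperative", "other", 2, 0, 0),
    ]
    return pd.DataFrame(rows, columns=["treatment", "site", "igrt_only",
                                       "art_boost", "art_initial"])


def fixture_manifest(n_adaptive_fractions: int = 46,
                     n_applied_adaptive: int = 30) -> pd.DataFrame:
    """Fraction manifest encoding the published cohort counts.

    Patients and the boost/initial split derive from :func:`table1_fixture`;
    the adaptive fractions are distributed over the ART patients and the
    first ``n_applied_adaptive`` of them carry the delivered=adaptive flag.
    """
    t1 = table1_fixture()
    n_boost = int(t1["art_boost"].sum())
    n_initial = int(t1["art_initial"].sum())
    n_igrt = int(t1["igrt_only"].sum())
    art_courses = ["boost"] * n_boost + ["initial"] * n_initial
    n_art = len(art_courses)
    rows = []
    # spread fractions over ART patients as evenly as possible
    base, extra = divmod(n_adaptive_fractions, n_art)
    applied_left = n_applied_adaptive
    for i, course in enumerate(art_courses):
        pid = f"ART{i + 1:02d}"
        n_frac = base + (1 if i < extra else 0)
        for f in range(n_frac):
            delivered = "adaptive" if applied_left > 0 else "scheduled"
            applied_left -= 1 if delivered == "adaptive" else 0
            rows.append({"patient_id": pid, "phase_id": f"{pid}_phase1",
                         "fraction_id": f"{pid}_f{f + 1}", "mode": "adaptive",
                         "course": course, "delivered": delivered})
    for i in range(n_igrt):
        pid = f"IGRT{i + 1:02d}"
        rows.append({"patient_id": pid, "phase_id": "", "fraction_id": "",
                     "mode": "igrt", "course": "", "delivered": ""})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Statistics report
# --------------------------------------------------------------------------

def _tr_dict(tr) -> dict:
    return {"method": tr.method, "statistic": tr.statistic, "p_value": tr.p_value,
            "n": tr.n, "estimate": tr.estimate,
            "ci": list(tr.ci) if tr.ci else None, "note": tr.note}


def statistics_report(metrics: pd.DataFrame, deviations: pd.DataFrame,
                      margin_df: pd.DataFrame) -> dict:
    """JSON statistics report keyed by figure/table analogue."""
    ctv = metrics[metrics["structure"] == "CTV"]
    sched = ctv[ctv["plan_type"] == "scheduled"].set_index("fraction_id")
    adapt = ctv[ctv["plan_type"] == "adaptive"].set_index("fraction_id")
    common = sched.index.intersection(adapt.index)
    eud_s = sched.loc[common, "eud_pct"].to_numpy()
    eud_a = adapt.loc[common, "eud_pct"].to_numpy()

    xs_s, f_s = ecdf(eud_s)
    xs_a, f_a = ecdf(eud_a)
    hom_s = sched.loc[common, "homogeneity_pct"].to_numpy()
    hom_a = adapt.loc[common, "homogeneity_pct"].to_numpy()
    hx_s, hf_s = ecdf(hom_s)
    hx_a, hf_a = ecdf(hom_a)

    report: dict = {
        "fig1a": {
            "ecdf_scheduled": {"x": xs_s.tolist(), "F": f_s.tolist()},
            "ecdf_adaptive": {"x": xs_a.tolist(), "F": f_a.tolist()},
            "median_eud_scheduled": float(np.median(eud_s)),
            "median_eud_adaptive": float(np.median(eud_a)),
            "scale_test": _tr_dict(scale_test(eud_s, eud_a, "ansari_bradley")),
            "location_test": _tr_dict(signed_rank_test(eud_a, eud_s)),
        },
        "fig1c": {
            "ecdf_scheduled": {"x": hx_s.tolist(), "F": hf_s.tolist()},
            "ecdf_adaptive": {"x": hx_a.tolist(), "F": hf_a.tolist()},
            "signed_rank": _tr_dict(signed_rank_test(hom_s, hom_a)),
        },
    }
    if len(eud_a) >= 40:
        est_a, ci_a, note = percentile_with_ci(eud_a, q=0.025)
        est_s, ci_s, _ = percentile_with_ci(eud_s, q=0.025)
        report["fig1a"]["p2_5_adaptive"] = {"estimate": est_a, "ci": list(ci_a),
                                            "note": note}
        report["fig1a"]["p2_5_scheduled"] = {"estimate": est_s, "ci": list(ci_s),
                                             "note": note}

    # motion statistics (fig 2 / fig 4 analogues)
    dev = delta_abs(deviations)
    fig4a = percentile_summary(dev, q=0.95)
    fig2 = {}
    fig4b = {}
    for param, sub in dev.groupby("parameter"):
        fig2[str(param)] = _tr_dict(correlations(
            np.abs(sub["inter_mm"]), np.abs(sub["intra_mm"]), "spearman"))
        fig4b[str(param)] = _tr_dict(signed_rank_test(sub["delta_mm"].to_numpy()))
    report["fig2"] = fig2
    report["fig4a"] = {
        "per_parameter": fig4a.reset_index().to_dict(orient="records"),
        "median_inter_p95": fig4a.attrs["median_inter_mm"],
        "median_intra_p95": fig4a.attrs["median_intra_mm"],
        "scale_tests": {
            str(p): _tr_dict(scale_test(sub["inter_mm"].to_numpy(),
                                        sub["intra_mm"].to_numpy(),
                                        "ansari_bradley"))
            for p, sub in dev.groupby("parameter")},
    }
    report["fig4b"] = fig4b

    # fig 3 analogue: scheduled-EUD ranks vs the three most mobile landmarks
    ranks = (pd.Series(eud_s).rank(method="average") - 1) / max(len(eud_s) - 1, 1)
    fr_dev = deviations.pivot_table(index="fraction_id", columns="parameter",
                                    values="inter_mm")
    fr_dev = fr_dev.loc[[f for f in common if f in fr_dev.index]]
    fig3 = {}
    from .landmark_stats import rank_adaptation_fit
    for param in (7, 4, 5):  # tongue back, hyoid craniocaudal, hyoid overall
        devs = fr_dev[param].to_numpy()
        fig3[str(param)] = {
            "linear": rank_adaptation_fit(ranks.to_numpy(), devs),
            "quadratic": rank_adaptation_fit(ranks.to_numpy(), devs, quadratic=True),
            "spearman": _tr_dict(correlations(eud_s, devs, "spearman")),
        }
    report["fig3"] = fig3
    report["table2"] = margin_df.to_dict(orient="records")
    return report


# --------------------------------------------------------------------------
# Report schema check
# --------------------------------------------------------------------------

def _schema_path() -> Path:
    return Path(__file__).parent / "schemas" / "report.schema.json"


def validate_report(report: dict, schema: dict | None = None) -> list[str]:
    """Validate the statistics report against the bundled JSON schema.

    Minimal structural validator (required keys + primitive types) adequate
    for the schema subset this project publishes.  Returns a list of
    violations; empty means valid.
    """
    if schema is None:
        schema = json.loads(_schema_path().read_text())
    errors: list[str] = []

    def check(node, spec, path):
        expected = spec.get("type")
        if expected == "object":
            if not isinstance(node, dict):
                errors.append(f"{path}: expected object")
                return
            for key in spec.get("required", []):
                if key not in node:
                    errors.append(f"{path}: missing required key '{key}'")
            for key, sub in spec.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{path}.{key}")
        elif expected == "array":
            if not isinstance(node, list):
                errors.append(f"{path}: expected array")
            elif "items" in spec:
                for i, item in enumerate(node):
                    check(item, spec["items"], f"{path}[{i}]")
        elif expected == "number":
            if node is not None and not isinstance(node, (int, float)):
                errors.append(f"{path}: expected number")
        elif expected == "string":
            if node is not None and not isinstance(node, str):
                errors.append(f"{path}: expected string")

    check(report, schema, "$")
    return errors


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------

def run_cohort(config: RunConfig | None = None, seed: int | None = None,
               output_dir: str | Path | None = None,
               write_volumes: bool = False) -> dict:
    """Run the whole analysis and write the report bundle.

    Emits per-fraction metrics CSV, deviation table CSV, the margin-vs-EUD
    table CSV, min-margin summary, statistics JSON, fraction manifest CSV,
    cohort-summary JSON and a config echo.  ``write_volumes`` additionally
    dumps per-fraction dose/mask NRRDs and displacement fields (large).
    """
    config = config or RunConfig()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config, seed=seed)
    metrics = fraction_metrics(cohort)
    deviations = deviation_table(cohort)
    manifest = build_manifest(cohort)

    results = []
    for phase_id, fractions in cohort.phases().items():
        try:
            results.append(analyze_phase(
                phase_id, fractions, cohort.phantom.ptv,
                config.exponents["tumor"], config.plan.prescription_gy))
        except Exception:  # quarantine, keep going
            logger.exception("phase %s failed; quarantined", phase_id)
    margin_df = margin_summary(results)

    min_margins = {r.phase_id: {pt: r.min_margin[pt] for pt in r.min_margin}
                   for r in results}
    report = statistics_report(metrics, deviations, margin_df)
    violations = validate_report(report)
    if violations:
        raise ValueError(f"statistics report failed schema validation: {violations}")
    summary = summarize_cohort(manifest)
    summary["n_phases_analyzed"] = len(results)
    summary["min_margin_by_phase"] = min_margins

    metrics.to_csv(out / "fraction_metrics.csv", index=False, float_format="%.6f")
    deviations.to_csv(out / "deviation_table.csv", index=False, float_format="%.6f")
    manifest.to_csv(out / "manifest.csv", index=False)
    margin_df.to_csv(out / "margin_table.csv", index=False, float_format="%.6f")
    (out / "statistics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "cohort_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    save_config(config, out / "config_echo.yaml")

    if write_volumes:
        vol = out / "volumes"
        vol.mkdir(exist_ok=True)
        gio.write_grid(vol / "reference_dose.nrrd", cohort.planner.reference_dose())
        for name in cohort.phantom.structures.names():
            gio.write_mask(vol / f"{name}.nrrd", cohort.phantom.structures[name])
        for fr in cohort.fractions:
            gio.write_grid(vol / f"{fr.fraction_id}_adaptive.nrrd", fr.adaptive_dose)
            gio.write_field(vol / f"{fr.fraction_id}_field.nrrd",
                            fr.displacement_field(), config.grid.spacing_mm)
        gio.write_sidecar(
            vol / "plan.json", config.plan.prescription_gy,
            config.plan.fractions_per_phase,
            {m.name: m.role.value for m in cohort.phantom.structures},
            config.exponents)

    return {"summary": summary, "report": report, "metrics": metrics,
            "deviations": deviations, "margin_table": margin_df,
            "phase_results": results, "cohort": cohort}
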