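# artdose

Dosimetric and geometric comparison of online-adaptive versus scheduled
(IGRT-style) radiotherapy plans, exercised end-to-end on a synthetic
head-and-neck phantom cohort.

The pipeline covers:

* **dose_metrics** — generalized equivalent uniform dose (gEUD, power-mean
  over voxel doses; tumor exponent −20, parotid 1.43, larynx 9.1) and the
  DVH panel (V100, D99/D95/D90, Dmin/Dmax, homogeneity Dmax−D99), all
  normalized to prescription.
* **geometry** — Euclidean-distance-transform margin operations: PTV
  expansion, stepwise inner-margin erosion producing the synthetic
  CTV_1–10 mm series, volume bookkeeping.
* **synthetic_cohort** — phantom anatomy (mobile "tongue" CTV, parotids,
  larynx, spinal cord inside a BODY), heavy-tailed inter-/intrafractional
  shift sampler with eight calibrated landmark readouts, an idealized dose
  shaper standing in for the planner, plan-selection policy, and
  ground-truth displacement fields.
* **accumulation** — displacement-field dose pullback (trilinear) onto the
  reference anatomy per treatment phase (≥ 3 fractions), the per-margin
  accumulated-EUD table, and the minimum adequate margin criterion
  (smallest margin with accumulated EUD > 95%).
* **landmark_stats** — |inter|−|intra| deltas, order-statistic percentile
  summaries, exact/approximate Wilcoxon signed-rank and rank-sum tests,
  Ansari-Bradley and Mood scale tests, Pearson/Spearman correlations with
  Fisher-z CIs, ECDFs, percentile confidence intervals, rank-vs-deviation
  fits.
* **pipeline / CLI** — orchestration, deterministic seeding, CSV/JSON/NRRD
  artifacts, report schema validation.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, one test class per
criterion. The full suite takes a couple of minutes on one CPU; the heavy
part is the default seeded cohort (8 phases × ≥ 3 fractions on a 64³ grid at
2 mm voxels), which is generated once per session.

## CLI

```sh
artdose run --seed 1 --out artdose_out          # full pipeline
artdose generate|metrics|accumulate|stats ...   # individual stages
artdose fixture --out fixture_manifest.csv      # published-cohort manifest
artdose import-rt <RTDOSE.dcm>                  # optional, needs pydicom
```

All stages accept `--config <yaml>` (see `artdose.config.RunConfig` for the
schema) and `--seed` to override the master seed; same config + seed
reproduces every output bit-identically.

Outputs: `fraction_metrics.csv` (per fraction × structure × plan type),
`deviation_table.csv` (fraction × landmark parameter), `margin_table.csv`
(margins 1–10 mm × {adaptive, scheduled} × {min, max, mean, median} over
phases), `statistics.json` (keyed by figure/table analogue and validated
against `src/artdose/schemas/report.schema.json`), `manifest.csv`,
`cohort_summary.json` and a YAML config echo. Grids and masks travel as
ASCII-encoded NRRD with a JSON plan sidecar.

## Conventions

* Arrays are (z, y, x), 0-based, world = origin + index·spacing at voxel
  centers; default grid 64³ at 2 mm isotropic.
* D_q is the order statistic at index ceil(q·n) of the descending-sorted
  voxel doses (no interpolation); percentiles in the statistics module use
  the ascending twin of the same convention.
* gEUD uses raw voxel doses; for negative exponents voxel doses are floored
  at 10⁻³ × prescription (floored voxels are counted and reported).
* Margins are realized by thresholding the Euclidean distance transform.
  The CTV_m series erodes the PTV (as opposed to expanding the CTV); the
  two coincide for convex shapes but differ for non-convex ones.
* All p-values are two-sided; signed-rank zeros follow Pratt; ties get
  midranks; no multiple-testing correction by default (Holm behind a flag).
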