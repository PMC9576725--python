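# siscreen

Analysis pipeline for a multiplexed siRNA viability screen with a cisplatin
co-treatment arm, plus a survival-biomarker scan of a registry-shaped tumor
cohort. The package simulates both data types from explicit generative
models, so every stage can be validated end to end against planted truth.

## Scientific problem

A genome-family siRNA screen (390 genes, triplicate 384-well batches)
measures two readouts per well — a viability signal and a cell count — with
and without a sub-lethal cisplatin dose. The questions are:

1. **Which knockdowns inhibit proliferation**, alone and/or only in
   combination with cisplatin (cisplatin *sensitizers*)?
2. **Does viability per cell** (viability / count) reveal a resistance
   signature — survivors of stronger knockdowns looking metabolically
   healthier?
3. **Is the expression of a candidate gene prognostic** in a tumor cohort,
   overall or only within carriers of a mutation geneset — scanned over
   48 conditions (2 endpoints × 2 split rules × 3 gender strata × 4 stages)?

## Pipeline

| Stage | Module | What it does |
|---|---|---|
| I/O | `siscreen.io` | Plate tables, results, cohort tables (clinical / expression / mutations) |
| QC | `siscreen.plate_qc` | z′-factor per plate/batch/arm/readout from siPLK1 vs siNC controls |
| Hits | `siscreen.normalize` | Per-plate log2 normalization vs siNC median; pooled-variance t-test; hit categories |
| Metrics | `siscreen.metrics` | Viability per cell, % growth inhibition, additive-null synergy |
| Survival | `siscreen.survival` | From-scratch Kaplan–Meier and log-rank; the 48-cell scan; mutation stratification |
| Simulation | `siscreen.simulate` | Generative screen and cohort models with planted effects |
| CLI | `siscreen.cli` | `siscreen qc / call-hits / metrics / synergy / survival-scan / survival-stratified / simulate / run-all` |

Key statistical definitions:

- **z′-factor** (STANDARD): `1 − 3(sd_pos + sd_neg) / |avg_pos − avg_neg|`;
  `> 0.5` EXCELLENT, `> 0` BORDERLINE, else FAIL. An `AS_PRINTED` variant
  (subtracted SDs) is available behind a flag (see `docs/methods.md`).
- **Hit per arm**: `p_count < 0.01` and `log2fc_count ≤ −1` (≥ twofold
  inhibition). Categories: `COMMON`, `CISPLATIN_SENSITIZED` (combined arm
  significant, significantly more inhibitory than the single arm),
  `SINGLE_ONLY`, `COMBINED_ONLY`, `NONE`. No multiple-testing correction.
- **Synergy**: observed combined change < sum of single-treatment changes
  minus a tolerance (default: replicate SE of the combined condition).
- **Prognosis call**: best (smallest) log-rank p over the 48 cells, direction
  from the observed-minus-expected events of the HIGH-expression group;
  `UNFAVORABLE` / `FAVORABLE` if `best_p < 0.05`, else `NONE`; tier
  `P01` / `P05` / `NS`.

## Worked example

```bash
python analysis/01_simulate_screen.py --seed 1     # 4608 wells, 37 + 9 planted hits
python analysis/02_plate_qc.py
python analysis/03_call_hits.py
python analysis/04_multiplex_metrics.py --seed 1
python analysis/05_simulate_cohort.py --seed 1
python analysis/06_survival_scan.py
python analysis/07_calibration.py --seed 1
```

Actual output at seed 1 — hit calling recovers exactly the planted truth
(37 common inhibitors, 9 cisplatin-sensitized genes, zero false calls):

```
category
NONE                    344
COMMON                   37
CISPLATIN_SENSITIZED      9
```

and the survival scan finds the planted expression-by-mutation interaction
only when restricted to mutation carriers:

```
        scan   gene   best_p        call tier  n_samples
unstratified TARGET 0.057915        NONE   NS        400
  stratified TARGET 0.000034 UNFAVORABLE  P01         91
```

Equivalent one-shot run via the CLI: `siscreen run-all --seed 1 --out results/run`.

## Known limitation: best-of-48 multiplicity

The scan reports the *minimum* p over 48 overlapping conditions without any
multiplicity correction, by design. The null calibration
(`analysis/07_calibration.py`) quantifies the consequence: on pure-null
cohorts (hazard ratio 1, n = 300), **80% of scans reach `best_p < 0.05`**
and only 20% are called `NONE` (50 seeds, seed 1), even though the
underlying single-cell log-rank is well calibrated (KS uniformity p ≈ 0.46
over 200 null datasets). A nominally significant `best_p` from this scan is
therefore descriptive, not confirmatory. This is also why one acceptance
test — which requires the unstratified scan to call `NONE` in ≥ 80% of
interaction cohorts — is structurally unattainable and left red.

See `docs/methods.md` for the generative models, parameter choices and all
numerical conventions.
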