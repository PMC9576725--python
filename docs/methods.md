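# Methods

## Screen normalization and testing

Raw counts and viabilities are log2-transformed per plate and centered on
the median of that plate's siNC wells (`nc_center="mean"` available).
Non-positive raw values and plates with fewer than two siNC wells are
rejected; missing values stay missing (never imputed as zero).

A gene's effect per arm is tested against the siNC wells of the *same plate
set* with a pooled-variance Student's t-test on the normalized values. Using
the same plates' controls means the per-plate median center cancels exactly
in the difference of means, so the test is invariant to plate-level offsets.
Measured type-I rate at nominal 0.01: 0.013 ± 0.003 (20 full-scale null
screens).

Hit calling uses per-arm significance `p_count < 0.01` AND
`log2fc_count ≤ −1` (inhibitory, at least twofold), with categories ordered
`COMMON` > `CISPLATIN_SENSITIZED` > `COMBINED_ONLY` / `SINGLE_ONLY` >
`NONE`. `CISPLATIN_SENSITIZED` additionally requires a combined-vs-single
contrast p < 0.01 with the combined arm more inhibitory. No
multiple-testing correction is applied at any stage — the thresholds are the
study's operating points, not error-controlled decisions.

## z′-factor

Two variants are implemented:

- `STANDARD` (default): `1 − 3(sd_pos + sd_neg)/|avg_pos − avg_neg|`, the
  canonical Zhang et al. definition.
- `AS_PRINTED`: `1 − 3(sd_pos − sd_neg)/|avg_pos − avg_neg|`, reproducing a
  typeset source equation that subtracts the SDs. It is kept behind a flag
  for comparability; it is always ≥ the standard value and should not be
  used for QC decisions.

Quality classes use strict inequalities: `> 0.5` EXCELLENT, `> 0`
BORDERLINE, otherwise FAIL. Control SDs are sample SDs (ddof = 1) and
require ≥ 2 wells per control.

## Survival analysis

Kaplan–Meier product-limit and the two-group log-rank test (hypergeometric
variance, chi-square with 1 df) are implemented from scratch; both were
verified against `lifelines` to ~1e-15 in the test suite (lifelines is a
test-only dependency). At ties, events precede censorings. An exact
permutation log-rank (full enumeration for n ≤ 12, sampled otherwise)
serves as a small-sample oracle; the asymptotic p typically differs from it
by 0.03–0.05 at n = 10 because of the permutation distribution's atom size.

Expression splits: `MEDIAN` assigns ties to LOW; `QUARTILE` takes
`> 75th percentile` as HIGH and `< 25th` as LOW (middle excluded), with
percentiles by NumPy's default linear interpolation. FPKM is converted to
`log2(TPM + 1)` via `TPM_i = FPKM_i / ΣFPKM × 1e6`, which is scale-invariant
and sums to 1e6 by construction.

The 48-cell scan enumerates endpoint {OS, DFS} × split {MEDIAN, QUARTILE} ×
gender {FEMALE, MALE, BOTH} × stage {I–IV} in that fixed order, filtering
samples before splitting. `best_p` is the minimum over valid cells (first
minimum wins ties in the fixed order); direction comes from the sign of
observed-minus-expected events in the HIGH group. Calls: `UNFAVORABLE` /
`FAVORABLE` when `best_p < 0.05`, else `NONE`; tiers `P01` / `P05` / `NS`.
The mutation-stratified scan reruns the same 48 cells on carriers of any
gene in the supplied geneset.

**Multiplicity.** The minimum over ~30 effectively independent cells is
reported uncorrected, mirroring the study design. Null simulation (HR = 1,
n = 300, 50 seeds) measures `best_p < 0.05` in 80% of scans — roughly
`1 − 0.95^30` — while the single-cell log-rank is well calibrated (KS
uniformity p ≈ 0.46 over 200 null datasets). Scan-level significance is
therefore exploratory only.

## Generative models

### Screen (`ScreenSimConfig`)

384-well plates: genes in columns 1–22 (352 per plate), siNC in column 23
and siPLK1 in column 24 (16 wells each). Per batch and arm, log2 count
effects combine a planted gene effect, a batch shift (SD 0.10), a global
cisplatin shift of −1 log2 on all combined-arm wells, and lognormal noise
with `σ_log2 = sqrt(ln(1 + cv²))/ln 2` (count CV 10%, viability CV 20%).
Viability multiplies count by a per-cell baseline (2.0 a.u.) inflated by
`resistance_gain · max(0, −effect)` (0.30/log2) for gene knockdowns —
survivors of stronger knockdowns look metabolically healthier — but *not*
for the siPLK1 control (−3 log2), matching the assay's transfection-control
behavior. Baseline count 1600.

### Cohort (`CohortSimConfig`)

Exponential survival with hazard
`baseline · hr_high^HIGH · hr_interaction^(HIGH ∧ carrier)`, where HIGH is
membership in the upper component of a two-component expression mixture
(means 2 and 4, SD 1) and carriers (25%) hold ≥ 1 mutation of a 3-gene
geneset. Independent exponential censoring; DFS is the minimum of a
recurrence process (0.7 × the death hazard) and death, so DFS ≤ OS always.
Defaults were set to registry-cohort shape: baseline hazard 0.000465/day
(median OS ≈ 49 months) and censoring 0.00077/day (median follow-up
≈ 2.5 years), giving ~38% observed deaths. Stage probabilities
(0.54, 0.24, 0.16, 0.06); five background mutation genes at 12% each.

Limits of realism: proportional hazards are exact, expression components are
Gaussian, censoring is non-informative, and there is no correlation between
stage and hazard — the cohort is a calibration instrument, not a synthetic
registry.

## Numerical conventions

- Sample SDs everywhere (ddof = 1).
- Viability per cell raises on a zero count (undefined, not infinite);
  missing values propagate.
- % growth inhibition = `(treat₉₆ − t₀) / (ctrl₉₆ − t₀) × 100`; undefined
  when the control did not change.
- Synergy flag is strict: observed < expected − tolerance.
- Reserved perturbation labels `NC`, `PLK1`, `EMPTY` are case-insensitive on
  input and canonicalized to uppercase.
- Per-repetition seeds: `(base · 1_000_003 + 7919 · i + 1) mod (2³¹ − 1)`.

## Known limitations

- No multiple-testing correction anywhere (by design); see the multiplicity
  note above.
- The additive synergy null is a plain sum of single-treatment changes, not
  Bliss or Loewe.
- The asymptotic log-rank p is anti-conservative versus the exact
  permutation p for n ≲ 12.
- One acceptance test (interaction discrimination requiring the unstratified
  scan to call `NONE` in ≥ 80% of interaction cohorts) is structurally
  unattainable given the measured ~80% best-of-48 null inflation and is left
  failing rather than weakened.
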