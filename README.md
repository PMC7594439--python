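# ehsra

Toolkit for an environmental heat strain risk index for workers in hot
workplaces, together with the full statistical pipeline that produces and
validates such an index:

- **`ehsra.core_index`** — the risk score: six min-max normalized variables
  (dry, natural wet-bulb and globe temperatures, air velocity, total
  metabolism, clothing insulation) combined as a scaled weighted sum, with
  the air-velocity term subtracted while dry temperature is below the
  35 °C skin threshold. Four risk bands (Low / Moderate / High / Very high
  at 12.02 / 15.88 / 17.56), repeated-measurement aggregation (mean for
  thermal, max for physiological variables) and the HRmax / tympanic
  screening rules.
- **`ehsra.sem_path_model`** — a one-latent-factor path model (six
  indicators → latent strain → tympanic temperature) fitted by maximum
  likelihood to a covariance or correlation matrix; standardized
  direct/indirect effect decomposition and goodness-of-fit indices
  (GFI, AGFI, NFI, CFI, IFI, RMSEA, normed χ²).
- **`ehsra.cutpoint_calibration`** — ROC curves of the score against
  dichotomized tympanic temperature (boundaries 37.5 / 38.0 / 38.5 °C),
  Mann–Whitney AUC with Hanley–McNeil 95% CIs, nearest-to-ideal cut-point
  selection and risk-band assembly.
- **`ehsra.validation`** — OLS regression of tympanic temperature on the
  score, plus a closed-form R² computable directly from a correlation
  matrix, SDs and the index constants (the calibrated moments yield
  R² = 0.75).
- **`ehsra.synthetic_cohort`** — a multivariate-normal cohort generator
  calibrated to the published means, SDs and 7×7 correlation matrix, with
  optional two-site mixing and range truncation, so every stage runs
  without field data.
- **`ehsra.io_cli`** — CSV/JSON IO with provenance headers and the `ehsra`
  command-line interface.

## CLI

```bash
ehsra simulate --n 201 --seed 42 --output cohort.csv        # synthetic cohort
ehsra compute  --input cohort.csv --output scored.csv       # score + risk band
ehsra develop  --input cohort.csv --report fit.json         # path-model fit
ehsra develop  --corr corr.csv --sd sd.csv --n 201 --report fit.json
ehsra cutpoints --input scored.csv --boundaries 37.5,38.0,38.5 --report cuts.json
ehsra validate --input scored.csv --report validation.json
ehsra validate --corr corr.csv --sd sd.csv --report validation.json  # closed form
```

Input CSVs are comma-separated with period decimals and a mandatory
header; the six required columns are `t_dry, t_wet, t_globe, v_air,
metabolism, clo` (°C, °C, °C, m/s, W, clo), optionally `tympanic,
heart_rate, age, subject_id, site`. Lines starting with `#` are
provenance comments. Exit codes: 0 success, 2 invalid input, 3 numerical
failure.

The default index calibration ships as JSON
(`src/ehsra/data/default_spec.json`); pass `--spec my_spec.json` to score
with different coefficients, normalization ranges or bands.

## Notes

- Scores are carried at full precision and reported at 2 decimals; inputs
  outside the calibration ranges are scored but flagged with a
  `CalibrationWarning` (no silent clipping).
- The default synthetic cohort is untruncated multivariate normal — the
  calibrated moments are exact, at the cost of occasional physically
  impossible tail values (e.g. negative air velocity). Use `--truncate`
  to enforce the calibrated ranges instead (this slightly distorts the
  moments).
- The shipped path model is the simple one-factor structure with no
  indicator error covariances; `PathModelSpec(error_covariances=...)`
  frees additional parameters when a richer topology is wanted.
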