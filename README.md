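# sparkspec

Analysis pipeline for optical emission spectra recorded during
electrosurgical sparking on tissue, aimed at discriminating normal from
abnormal breast tissue. The package covers the full chain:

- **spectra_io** — plain-text spectrum files + cohort manifest, QC
  exclusion accounting (`apply_qc`).
- **synthetic_data** — a synthetic spark-spectrum cohort generator
  (Gaussian emission lines, tissue-dependent fold-changes, per-patient
  random effects, detector noise, manifest-level QC failures) standing in
  for the request-only clinical data.
- **preprocessing** — flanking-annulus local baselines, line SNR, the
  carbon-line quality gate (spectra with C 247.856 nm SNR below 20x the
  surrounding-baseline SD are excluded), and total-intensity
  normalization.
- **features** — peak detection, catalogue matching (17-entry default
  catalogue: P, Zn, C, Fe, Mg, Ca, Na, K atomic lines plus the C2 band at
  516.49 nm), panel selection (SNR > 20 and occurrence >= 5% of spectra),
  baseline-subtracted windowed integration into feature vectors, and
  standardized-mean-difference feature scores.
- **classify** — leave-one-patient-out cross-validation of an RBF
  support-vector classifier with per-patient accuracy, sensitivity,
  specificity, PPV and NPV plus arithmetic means over patients.
- **pipeline_cli** — the `sparkspec` command orchestrating everything.

## CLI

```sh
# write a synthetic cohort (manifest + spectrum files) to ./cohort
sparkspec simulate -o cohort

# analyse it end to end; writes panel.csv, metrics.csv, predictions.csv,
# run_log.json to ./out
sparkspec run -o out --set paths.manifest=cohort/manifest.csv \
    --set paths.spectra_dir=cohort/spectra

# render the per-patient metrics table (optionally a heatmap PNG)
sparkspec report out/metrics.csv --figure out/metrics.png
```

All thresholds are config keys; pass `-c config.yaml` and/or repeated
`--set key=value` overrides (e.g. `--set features.min_snr=25`,
`--set simulation.seed=7`). Exit codes: 0 success, 2 config error, 3 data
error, 4 analysis error.

## Data formats

- Spectrum file: CSV with header `wavelength_nm,intensity`, one file per
  acquisition; round-trips losslessly.
- Manifest: CSV with columns `spectrum_id, patient_id, sample_id,
  tissue_label, qc_status, file`; `tissue_label` is `normal` or
  `abnormal`, `qc_status` is `ok` or an exclusion category
  (`instrument_contamination`, `poor_spectral_quality`, `memory_error`,
  `low_carbon_snr`).
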