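# gaitmark

Gait analysis for two-foot, 8-sensor force-sensitive insole recordings:

- **segmentation** — contact detection from per-foot total vertical force,
  per-sample phase labels (double support, left/right single support),
  stride segmentation anchored at double support followed by right single
  support, per-cycle timing parameters (stance/swing/double-support/step,
  in seconds and % of stride), and one-sided rejection of overlong strides
  (duration > mean + 2·SD).
- **features** — per-subject average / median / SD / IQR of each stride
  parameter (42 kinematic variables incl. the gait-speed and
  timed-up-and-go covariates) plus whole-trial mean / median / SD / IQR of
  each foot's total force (8 dynamic variables), with voltage
  normalization for uncalibrated hardware.
- **stats** — pooled-variance two-sample t-tests (healthy minus patient,
  df = n₁+n₂−2), Bonferroni control with a fixed factor of 50
  (0.05/50 = 0.001), and Mann–Whitney ROC analysis (patient group as
  positive, no orientation flipping; Hanley–McNeil SE, normal 95% CI)
  gated on the corrected t-test threshold.
- **synthetic_gait** — a programmable insole-gait simulator (two-peak
  stance force curve, heel-to-toe sensor activation, stride-to-stride
  variability, group contrasts, uncalibrated-voltage mode) with
  ground-truth event sidecars, used throughout the test suite.
- **io_formats** — tab-delimited recordings in the public gait-database
  layout (time, 8 left sensors, 8 right sensors, optional totals),
  metadata CSV, long-format feature tables.
- **pipeline_cli** — end-to-end orchestration with YAML config, QC plots
  and a provenance run log.

## CLI

```sh
gaitmark simulate --out cohort/ --n-hs 8 --n-pd 8 --duration 60 --seed 1
gaitmark segment cohort/HS000.txt --out cycles.csv --threshold 20 --min-phase 0.05
gaitmark features --data-dir cohort/ --meta cohort/metadata.csv --out features.csv
gaitmark compare --features features.csv --meta cohort/metadata.csv --out report/
gaitmark run --config run.yaml        # full pipeline from a YAML config
```

`gaitmark run` writes `cycles.csv`, `features.csv`, `ttest_kinematic.csv`,
`ttest_dynamic.csv`, `roc.csv`, QC figures, `config.yaml` and
`run_log.json` into the configured output directory; reports are
byte-stable for a fixed seed.

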