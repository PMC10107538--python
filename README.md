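# neoseize

Early prediction of electrographic seizures in neonatal hypoxic-ischemic
encephalopathy (HIE) from the first hours of life, re-implemented as a tested
pipeline:

- **`data_io`** — EDF read/write, montage-label normalization, selection of the
  earliest good-quality 1-h epoch (before 12 h of age and at least 1 h before
  the first seizure), artifact masking, and the 2-channel F3-C3/F4-C4
  (aEEG-style) derivation.
- **`qeeg_features`** — the quantitative EEG background battery: band powers
  (delta/theta/alpha/beta), relative power, spectral flatness/difference/edge
  frequency, range-EEG margins and asymmetry, interburst-interval (IBI)
  detection and statistics, amplitude skewness/kurtosis, Higuchi fractal
  dimension, brain symmetry index and coherence — plus a discontinuity-weighted
  copy of every non-IBI feature and the ASM/hypothermia adjusters.
- **`cohort_features`** — clinical/qualitative predictor assembly, mean
  imputation with a 50 % missingness cutoff, seizure-burden summaries
  (total/max-hourly burden, status epilepticus).
- **`synthetic_data`** — a cohort generator (burst/IBI renewal EEG model plus
  class-conditional clinical distributions) so that every downstream stage is
  testable without access to the original recordings, which are not deposited.
- **`prediction`** — nested leave-one-out cross-validation (random forest for
  clinical/qualitative features; depth-limited gradient boosting with 40
  iterations and learning rate 0.1 for quantitative features) and late-stage
  logit-mean fusion of model probabilities.
- **`evaluation`** — MCC, AUC, sensitivity/specificity/PPV/NPV at the
  equal-sensitivity/specificity operating point, stratified bootstrap CIs,
  Hotelling–Williams test for dependent correlations, Cohen's kappa, and
  reconstruction of published operating points from printed rates.

## CLI

```sh
# synthetic cohort: EDFs + clinical.csv/qualitative.csv/labels.csv/seizures.csv
neoseize simulate --n-subjects 50 --duration-s 3600 --seed 1 --out cohort/

# quantitative features from one EDF (+ optional artifact/seizure CSVs)
neoseize extract --edf cohort/S0000.edf --seizures sz.csv --out features.csv

# seizure-burden summaries
neoseize metrics --seizures cohort/seizures.csv --out burden.csv

# nested-LOOCV out-of-fold predictions (fuses probabilities for combo modes)
neoseize train --mode clinical --clinical cohort/clinical.csv \
    --labels cohort/labels.csv --seed 1 --out predictions.csv

# metric report with bootstrap CIs
neoseize evaluate --predictions predictions.csv --out report.json

# rebuild a confusion matrix from published sensitivity/specificity
neoseize operating-points --sensitivity 60.4 --specificity 77.1 --n-pos 53 --n-neg 109
```

Annotation CSVs use columns `onset_s` (or `onset_h`), `duration_s` and an
optional `label`; artifact onsets are seconds from record start, seizure
onsets are hours after birth.

## Conventions

- Time: seconds from record start internally, hours after birth at
  interfaces; intervals are half-open `[start, end)`.
- Amplitude: µV throughout; EDF files are written EDF+-style with physical
  dimension `uV` (unknown dimensions are assumed µV with a warning).
- Kurtosis is non-excess (normal = 3); relative band powers sum to 1 over the
  four bands; the IBI weighting uses the IBI *fraction* (percentage / 100).
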