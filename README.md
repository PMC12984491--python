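# cardiovcg

ECG and vectorcardiogram (VCG) feature extraction with cardiomyopathy
phenotype discrimination, plus a synthetic 12-lead ECG cohort generator with
per-record ground truth so the full pipeline can be exercised and validated
without access to restricted clinical data.

The pipeline covers:

- **I/O** (`cardiovcg.ecg_io`): 12-lead records as WFDB (format 16) or CSV,
  manifest tables, Goldberger limb-lead algebra, report-text exclusion rules
  (paced rhythm, bundle branch block, atrial fibrillation, ...) with negation
  guards, and one-ECG-per-patient selection.
- **Delineation** (`cardiovcg.delineate`): template-correlated R-peak
  detection, prominence-based P/T delineation, QRS bound refinement with a
  non-decimated dyadic wavelet stage plus amplitude/slope checks, and
  median-of-medians pooling into fixed global wave windows.
- **Median beats** (`cardiovcg.median_beat`): 850 ms R-aligned mean
  heartbeats, PR-baseline referenced, assembled into an 8-lead matrix
  calibrated on lead V5.
- **VCG features** (`cardiovcg.vcg_features`): Kors regression projection to
  X/Y/Z, P/QRS/T loop singular-value summaries (σ2/σ1, ln non-dipolar ratio,
  planarity), loop magnitudes and time–voltage areas, spatial P–QRS and QRS–T
  angles, and ventricular-gradient magnitude/orientation — a stable registry
  of 41 named features.
- **Scalar features** (`cardiovcg.scalar_features`): per-lead P/Q/R/S/T
  amplitudes vs the isoelectric PR baseline, R/S ratios, interval/duration
  features (including the T-index), spectral moments and time-domain
  skewness/kurtosis, machine-feature passthrough.
- **Statistics** (`cardiovcg.group_stats`): Mann–Whitney U (exact for small
  tie-free samples), Cliff's delta, risk difference, Table-style group
  comparisons and top-k feature ranking.
- **Models** (`cardiovcg.ml_eval`): missing-data handling (drop-3 +
  complete-case), L1 logistic regression (liblinear, C=0.1, fold-internal
  z-scoring) and gradient-boosted trees, stratified 5-fold out-of-fold
  evaluation with AUC-ROC / AUC-PR (both mean-across-folds and pooled
  conventions) and Youden-threshold sensitivity/specificity for the three
  binary tasks (HCM vs DCM-I, HCM vs DCM-NI, HOCM vs HNCM).
- **Simulator** (`cardiovcg.synth_cohort`): parametric 3D dipole-loop beats
  projected through the exact right-inverse of the Kors matrix, with
  phenotype presets encoding published group contrasts (R amplitudes, QRS
  duration, T-loop energy, ventricular-gradient orientation, RR /
  tachycardia fraction) and full ground truth per record.

## CLI

```sh
cardiovcg simulate --out sim/ --seed 7 --format wfdb    # synthetic cohort
cardiovcg extract --manifest sim/manifest.csv --out run/
cardiovcg compare --features run/features.csv --labels run/labels.csv \
    --groups HCM,DCM-I --out run/compare.csv
cardiovcg traineval --features run/features.csv --labels run/labels.csv \
    --task HCM_vs_DCM-I --model l1_logistic --out run/cv.json
cardiovcg all --out study/ --seed 7                     # end-to-end study
```

`cardiovcg all` accepts a YAML config, e.g.

```yaml
seed: 7
profiles: {HCM: 50, DCM-I: 50}
groups: [HCM, DCM-I]
tasks: [HCM_vs_DCM-I]
```

Outputs per run: `features.csv`, `labels.csv`, `registry.json`, `qc_log.csv`,
`compare.csv`, `metrics.json`, per-task `roc_points_*.csv`, and `report.md`
with the seed and config hash embedded.

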