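# nirsqc

Automated channel-wise signal quality control for functional near-infrared
spectroscopy (fNIRS) recordings.

The package implements a full segment-level quality-control pipeline for
dual-wavelength optical recordings:

1. **I/O** (`nirsqc.signal_io`) — a minimal continuous-wave SNIRF dialect
   (HDF5), Homer-style `.nirs`/`.mat` files, CSV label files and CSV/JSON
   quality reports. Note: the `.nirs` field `d` is interpreted as *raw
   light intensity* (the `.nirs` convention); the pipeline starts from raw
   intensity.
2. **Hemodynamics** (`nirsqc.hemodynamics`) — optical density conversion
   (natural log of the ratio to the temporal mean) and the modified
   Beer–Lambert inversion to oxy/deoxyhemoglobin concentration changes in
   µM, with a fixed DPF of 6 or an age-dependent DPF when the subject age
   is known.
3. **Quality indices** (`nirsqc.quality_indices`) — coefficient of
   variation (CV), scalp coupling index (SCI), cardiac peak spectral power
   (PSP) and a windowed composite quality index (CQI).
4. **Cardiac band fitting** (`nirsqc.cardiac_band`) — the subject-specific
   cardiac frequency band: Welch PSD (Hamming, 50 % overlap, dB),
   Savitzky–Golay smoothing (order 3), cubic aperiodic (1/f) removal in dB,
   prominence-gated peak detection, Gaussian peak fitting (CF, FWHM,
   FW10M) and the band `median(CF) ± median(FW10M)/2` over the channels
   preselected with CQI/SCI/PSP gates (CQI threshold relaxed in 0.05
   steps when no channel passes).
5. **Scalograms** (`nirsqc.scalogram`) — band-filtered Morlet CWT
   magnitude on a log-spaced grid, per-channel pooled min–max
   normalization, frequency-row standardization anchoring the cardiac
   band at row 30, bilinear time rescaling to 224 columns and jet RGB
   rendering (224×224×3).
6. **Classifier** (`nirsqc.classifier`, `nirsqc.nn`) — a compact
   from-scratch CNN (3 conv–norm–ReLU–pool blocks, global average pool,
   2-way softmax) in plain numpy, trained with Adam, weighted
   cross-entropy, L2 weight decay, on-the-fly augmentation and early
   stopping, under a subject-wise stratified protocol (90/10 development
   vs. holdout, k-fold CV, or an 80:10:10 train/val/test split).
7. **Evaluation** (`nirsqc.evaluation`) — confusion-matrix metrics with
   low-quality as the positive class, CV/SCI baselines, McNemar with
   continuity correction, Friedman, Wilcoxon signed-rank (exact for
   n ≤ 12) with Benjamini–Hochberg adjustment, and Cliff's δ.
8. **Synthetic data** (`nirsqc.synthetic`) — a fully seeded simulator of
   resting-state recordings with cardiac/Mayer/respiratory components,
   1/f drift, and per-segment low-quality modes (coupling loss, motion
   bursts, saturation) with ground-truth labels.

## Test

```sh
python -m pytest -q tests/
```

The suite generates all of its data programmatically (no fixture files);
the end-to-end classifier test trains the CNN on ~400 synthetic
scalograms and takes a few minutes on one CPU.

## CLI

The console script `nirsqc` wires the modules into two pipelines —
apply-a-model and train-a-model:

```sh
# generate a labeled synthetic dataset
nirsqc --seed 1 --out run/sim simulate --subjects 10 --channels 8 --duration 300 --low-fraction 0.4

# per-subject cardiac band estimates
nirsqc --out run/bands fit-band 'run/sim/*.snirf'

# train + evaluate against the CV/SCI baselines (subject-wise 80:10:10)
nirsqc --seed 1 --out run/train train 'run/sim/*.snirf' --labels run/sim/labels.csv

# apply a trained model
nirsqc --out run/pred predict 'run/sim/*.snirf' --model run/train/model

# score a report against labels; summarize channel quality percentages
nirsqc --out run/eval evaluate --report run/pred/sim000_quality.csv --labels run/sim/labels.csv
nirsqc --out run/summary report run/pred/*_quality.csv
```

All subcommands accept `--config <yaml>` (unknown keys are rejected) and
write a `run_manifest.json` (config hash, seed, version) beside their
outputs. Runs are deterministic given (config, seed).

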