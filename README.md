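# flimpipe

Simulation and analysis of point-scanning fluorescence lifetime imaging
(FLIm) data for intraoperative tissue discrimination, built so that every
stage is verifiable against synthetic ground truth:

- **simulate** — a four-band, time-multiplexed instrument model: IRF-convolved
  exponential decays digitized at 80 ps with per-channel SNR control,
  white-light frames with a blue aiming-beam spot, grayscale histology
  annotation maps, and multi-patient cohorts across three imaging contexts
  (in vivo pre-resection, ex vivo specimen, in vivo tumor bed).
- **process** — background subtraction, channel demultiplexing, SNR
  estimation, and constrained-least-squares deconvolution on a multi-scale
  discrete Laguerre basis (nonnegative, non-increasing impulse response,
  solved exactly via the dual NNLS). Yields three average lifetimes and
  three spectral intensity ratios per point.
- **coregister** — HSV-threshold aiming-beam localization, annotation-map
  label assignment (10 px radius), heterogeneous-neighborhood exclusion,
  30 dB SNR threshold, and per-patient/per-context ±2.5 MAD outlier removal.
- **discriminate** — per-patient Wilcoxon rank-sum tests, ROC-AUC, average
  precision, Cohen's d between contexts, and a six-parameter Fisher LDA
  variable with per-scan min-max scaling.
- **visualize** — SNR-weighted Shepard (inverse-distance) heat maps
  alpha-blended onto white-light frames.

## CLI

All stages share a YAML config (see `flimpipe/config.py` for the schema and
defaults) and a run directory with documented CSV/PNG/JSON intermediates:

```sh
flim all --seed 1 --run-dir runs/demo              # full pipeline
flim simulate --config cfg.yaml                     # or stage by stage
flim process --run-dir runs/demo
flim coregister --run-dir runs/demo
flim discriminate --run-dir runs/demo
flim visualize --run-dir runs/demo
```

Outputs per scan: `waveforms.csv` (one row per point, one column per
sample), `measurements.csv` (six FLIm parameters + SNR per point),
`positions.csv`, `labeled.csv` (labels + filter flags), `report.json`;
per run: `summary.csv` (per-context mean AUC/AP per parameter and for the
LDA variable), `effect_sizes.csv`, `filter_accounting.csv`, and heat-map
overlays under `heatmaps/`. Runs are byte-identical for a fixed seed.

## Notes

- Simulator tissue-class parameters are documented assumptions chosen to
  produce realistic contrast, not published tissue constants.
- Spectral channel 4 is simulated but excluded from analysis parameters;
  the intensity-ratio denominator uses channels 1–3 (configurable).
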