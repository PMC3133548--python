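# nirstrial

Single-trial classification of motor-imagery fNIRS signals, implemented as a
tested, reusable pipeline:

1. **`synthgen`** — forward simulator for block-design dual-wavelength fNIRS
   recordings (20 s rest / 15 s stimulation, 12 trials per condition, 100 Hz,
   three channels at 760/870 nm): gamma-kernel hemodynamic responses, linear
   drift, slow physiological oscillations, white noise, and a Beer–Lambert
   forward optical model producing raw detector intensities with known ground
   truth.
2. **`preproc`** — ambient-light subtraction, 7th-order Chebyshev type-II
   low-pass (≥20 dB attenuation from 5 Hz) with decimation 100 → 10 Hz,
   modified Beer–Lambert inversion (DPF 6.75 / 6.50) to Δ[O₂Hb]/Δ[HHb] in
   µmol/l, and full-recording linear detrending. Every step is logged and
   replayable bit-identically.
3. **`epochs_stats`** — trial epoching against the immediately preceding rest
   baseline, paired t-tests of stimulation vs. rest means, SNR
   (mean / sample SD), and channel/subject exclusion rules.
4. **`features`** — mean, unbiased variance, adjusted sample skewness and
   excess kurtosis on baseline-corrected stimulation traces restricted to
   half-open analysis windows `[start, end)` on the 1-s grid
   (starts 1–11 s, ends 5–15 s; 93 windows).
5. **`flda_search`** — hand-rolled Fisher linear discriminant
   (`w = (S_w + λI)⁻¹(m_a − m_b)`, midpoint threshold), leave-one-out
   cross-validation, and the exhaustive search over
   3 channels × 93 windows × 15 feature subsets = 4185 combinations with
   deterministic tie-breaking (simplest model first).
6. **`report`** — group aggregation of per-subject best combinations
   (mean/SD/range of accuracies, channel and feature selection counts),
   Pearson feature–accuracy correlations, keystroke error rate. Packaged
   fixtures transcribe the published per-channel amplitude/SNR table and the
   per-subject result table.

Support modules: `optics` (packaged extinction-coefficient table, absorbance
algebra), `pipeline` (end-to-end orchestration, amplitude calibration,
Monte-Carlo recovery), `io` (CSV/HDF5), `cli`.

## CLI

```bash
nirstrial simulate   --config cfg.yaml --seed 3 --out sim/      # raw.csv, events.csv, ground_truth.csv
nirstrial preprocess --in sim/raw.csv --events sim/events.csv --out hemo.csv
nirstrial classify   --features features.csv --out result.json  # exhaustive search
nirstrial report     --out report.json --markdown report.md     # group summary
```

`cfg.yaml` holds `GeneratorConfig` overrides, e.g.:

```yaml
n_trials_per_condition: 12
amp_o2hb: {MI-simple: [0.101, 0.054, 0.038], MI-complex: [0.192, 0.095, 0.065]}
white_noise_sd: 0.05
```

## Notes

- Amplitude semantics: `GeneratorConfig.amp_*` are peak amplitudes of the
  isolated single-trial response; `pipeline.calibrate_amplitudes` converts
  stimulation−rest mean targets into peaks by measuring and inverting the
  (linear) generator→pipeline response map per event table, including HRF
  tail spill-over into the following rest phase.
- Conventions that the underlying description leaves open (Chebyshev type,
  causal vs. zero-phase filtering, MBLL reference window, SNR averaging
  domain, kurtosis convention, CV fold scheme, tie-breaking) are explicit
  keyword arguments with documented defaults.
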