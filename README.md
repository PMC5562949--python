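# autoregwtc

Cerebral autoregulation monitoring for neonatal and pediatric ECMO from
routine bedside signals: minute-sampled mean arterial pressure (MAP, mmHg)
and cerebral tissue oxygen saturation (SctO2, %, near-infrared
spectroscopy).

A healthy cerebral circulation buffers slow blood-pressure swings; when
autoregulation fails, cerebral perfusion becomes *pressure-passive* and
SctO2 follows MAP in phase. `autoregwtc` detects this state with wavelet
transform coherence (WTC), which makes no stationarity or linearity
assumptions about the two signals:

- Morlet (ω₀ = 6) continuous wavelet transforms W_X, W_Y of the detrended,
  despiked, gap-segmented signals;
- cross-wavelet spectrum W_XY = W_X·W_Y\* and squared coherence
  R²(n, s) = |S(s⁻¹W_XY)|² / (S(s⁻¹|W_X|²)·S(s⁻¹|W_Y|²)), with S a
  Gaussian-in-time, boxcar-in-scale smoothing operator;
- Monte-Carlo significance of R² against 300 pairs of independent AR1
  (red-noise) surrogates matched to each signal's lag-1 autocorrelation
  (the 95 % null threshold comes out ≈ 0.71–0.73 in the analysis band);
- the relative phase Δφ(n, s) binned into in-phase (0 ± π/4), antiphase
  (π ± π/4) and two quadrature ranges;
- **P(s)** — the percentage of usable time with significant *in-phase*
  coherence per scale — and its mean over Fourier periods of 8–32 min
  (0.0005–0.002 Hz), **Pmean**, the scalar autoregulation-impairment
  index.

Companion modules score neuroimaging abnormalities (weighted
bleeding/parenchymal/ventricular severities; normal / mild-moderate /
severe categories), run the cohort statistics linking index to outcome on
the packaged 25-patient tables, and generate synthetic recordings and
cohorts with known ground truth. See `docs/methods.md` for the full
methodological account.

## Worked example

Generate a day-long synthetic recording in which minutes 300–900 are
pressure-passive (90 % of the SctO2 band variance driven by MAP), with a
15-min transport gap and occasional spikes, then run the full pipeline:

```sh
cat > demo_synth.yaml <<EOF
n_minutes: 1440
coupling_strength: 0.9
coupling_epochs: [[300, 900]]
spike_rate: 1.0
gap_spec: [[1000, 15]]
EOF
autoregwtc synth pair -o demo.csv -c demo_synth.yaml --seed 11
autoregwtc index demo.csv -o demo_report.json --seed 7
```

which prints

```
wrote demo.csv (600 coupled minutes of 1440)
Pmean = 40.6% (1425 usable min); wrote demo_report.json, demo_report.md
```

The index (40.6 %) tracks the ground truth: 600 of 1440 minutes — 42 % of
the recording — were coupled. The JSON report carries the per-scale,
per-phase-bin P(s) profile, segment bookkeeping and every setting; a null
recording (`coupling_strength: 0`) scores below 5 % and a fully coupled
one above 80 %. `autoregwtc wtc demo.csv -o field.npz --plot wtc.png`
saves the R²/phase/significance arrays and a heatmap in the style of
bedside WTC displays.

The packaged-cohort analysis:

```sh
autoregwtc cohort -o cohort_report.json
```

```
cohort n=25: R=0.66, p=0.00029; wrote cohort_report.json
```

i.e. across the 25 patients the autoregulation index explains a large
share of the neuroimaging-score variation (Pearson R = 0.66); the report
also contains per-age-group results (neonates R = 0.86, children
R = 0.54), category counts (8 normal / 7 mild-moderate / 10 severe) and
the exploratory regressions on ECMO duration, blood-gas deltas and
anticoagulation, none of which reach significance.

All subcommands: `preprocess`, `wtc`, `index`, `cohort`, `synth pair`,
`synth cohort`, `print-config`. Every default is visible via
`autoregwtc print-config`; exit codes distinguish input (2),
configuration (3) and computation (4) failures.

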