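# Methods

## The problem

Patients on extracorporeal membrane oxygenation (ECMO) are at high risk of
intracranial hemorrhage and ischemia. A healthy cerebral circulation
autoregulates: slow swings in mean arterial pressure (MAP) are buffered and
do not propagate into cerebral blood flow. When autoregulation fails, flow —
and with it cerebral tissue oxygen saturation (SctO2, measured by
near-infrared spectroscopy) — follows pressure passively. `autoregwtc`
quantifies this pressure-passive state from routine bedside recordings:
minute-sampled MAP and SctO2, collected continuously over an ECMO run that
may last days, interrupted by transport gaps, contaminated by spike
artifacts and slow drifts.

## Preprocessing

Spike artifacts are removed by linear interpolation between neighbouring
samples. Detection is automated: a sample adjacent to a first difference
whose magnitude exceeds `spike_z` (default 5) robust standard deviations
(1.4826 × MAD of the first differences; mean absolute deviation as fallback
when the MAD degenerates to zero) is flagged. Both endpoints of an outlying
difference are flagged, so spikes at either end of the record are caught;
flagged endpoints take the nearest surviving value. The procedure is a
reproducible, configurable stand-in for visual inspection and is idempotent
on physiological signals.

The recording is then split at gaps into contiguous segments where both
signals are valid. Segments shorter than `min_segment_len` (default 256
samples = 4 × the largest analysis scale) are discarded, so every retained
segment supports the full scale range outside severe edge effects. Slow
drifts are removed per segment — never across a transport gap, where a
global polynomial would leak drift between disconnected episodes — by
ordinary least-squares fitting of a second-order polynomial in time and
keeping the residuals. The residuals are mean-zero and orthogonal to
{1, t, t²} by construction. The ordering is fixed: spikes → segmentation →
per-segment detrend.

## Wavelet transform coherence

Each detrended segment pair is analyzed with the continuous wavelet
transform using the Morlet mother wavelet
ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2) with ω₀ = 6, evaluated in the Fourier
domain with zero padding to the next power of two, with the √(Δt/s)
normalization. Scales follow s_j = s₀·2^(j·dj) with s₀ = 2 min and
dj = 1/12 octave, extended until the equivalent Fourier period
λ = 4πs/(ω₀ + √(2+ω₀²)) ≈ 1.033·s passes 64 min — ample margin above the
32-min band edge. The cone of influence (COI) is the e-folding time √2·s of
the Morlet envelope, expressed per time point as the largest trustworthy
period; everything above it is excluded downstream from both the
significance mask and the index denominators.

The cross-wavelet transform W_XY = W_X·W_Y* carries joint power in its
modulus and the relative phase Δφ in its argument. The squared coherence is

    R²(n,s) = |S(s⁻¹·W_XY)|² / ( S(s⁻¹·|W_X|²) · S(s⁻¹·|W_Y|²) )

where the smoothing operator S is a Gaussian along time with standard
deviation equal to the scale, followed by a boxcar across scales of 0.6
octave, both normalized to unit mass. The scale boxcar uses the
fractional-end construction of the standard cross-wavelet toolbox
(a `0.6/(2·dj)`-step half-width rounded with fractional end weights,
zero-padded "same" convolution): with the naive renormalized-boxcar reading
the Monte-Carlo null threshold comes out near 0.74 instead of the ~0.71
that the established convention (and the published critical band) yields.
Without any smoothing the ratio degenerates to exactly 1 — the test suite
keeps a regression test of this degeneracy. Phase is the argument of the
smoothed cross spectrum.

## Significance against red noise

Slow physiological fluctuations are well modelled as first-order
autoregressive (AR1) noise, so the null for MAP–SctO2 coherence is a pair
of *independent* AR1 processes matched to each signal: φ is the lag-1
sample autocorrelation and the innovation variance follows the stationary
relation σ² = var·(1−φ²). An ensemble of 300 surrogate pairs (Gaussian
innovations, ≥100-sample burn-in) is processed with identical wavelet and
smoothing settings. Null R² values are pooled per scale across all time
points outside the COI — the surrogates are stationary, so the null is
time-invariant and pooling beats noisy per-cell quantiles — and the
per-scale 95th percentile is the critical value. Observed points exceeding
it (outside the COI) are significant. At minute sampling, 1440-sample
segments and φ ∈ [0.7, 0.95], the band threshold is nearly flat at ≈ 0.71,
essentially independent of φ.

## The autoregulation index

The relative phase is binned into four quadrants: in-phase (0 ± π/4),
antiphase (π ± π/4) and two asynchronous quadrature bins (±π/2 ± π/4);
bins are lower-inclusive/upper-exclusive and partition the circle.
Pressure-passive perfusion produces significant *in-phase* coherence, so
P(s) is the percentage of usable time (inside valid segments, outside the
COI — excluded from numerator and denominator alike, since counting COI
points would deflate P(s) for short recordings) at which coherence is
significant with in-phase Δφ. Multi-segment recordings pool counts before
dividing, i.e. the percentage is time-weighted over the whole run. The
scalar index Pmean is the unweighted mean of P(s) over scales whose period
lies in [8, 32] min, endpoints inclusive on the discrete grid; this band
(0.0005–0.002 Hz) is where pressure-passive coupling concentrates. The
pair ordering is fixed as x = MAP, y = SctO2; the arrow in "MAP→SctO2"
names that ordering, not a causal analysis.

## Neuroimaging scoring and cohort statistics

Imaging abnormalities are rated 0–3 in three categories (bleeding,
parenchymal lesions, ventricular dilatation), weighted and summed. The
weight factors belong to a previously validated ECMO scoring system and
are not re-derived here; they are a required configuration input with no
default. The category boundaries of the total are fixed: 0 → normal,
(0, 6] → mild-to-moderate, > 6 → severe. The 6.0 boundary goes to
mild-to-moderate — the only assignment consistent with the published
category counts — and totals above the nominal 18 ceiling are accepted as
severe.

The packaged cohort tables (25 patients: characteristics, indices and
scores, blood-gas deltas, anticoagulation summaries) are transcribed
verbatim; one physiologically impossible coagulation entry (patient 14's
PTT minimum of 830 s, above its own mean) is carried verbatim and flagged
by a validation warning rather than rejected. Blood-gas deltas follow the
clinical convention: pH and PaO2 change from the pre-ECMO minimum to the
on-ECMO maximum; PCO2 from the pre-ECMO maximum to the on-ECMO minimum, so
the usual CO2 washout is negative. The index–score association is the
Pearson correlation on untransformed values with the two-sided t-test
(n−2 df); regressions are ordinary least squares with intercept. Group
analyses (whole cohort, neonates ≤ 4 weeks, children) are the same
operations on subsets, with no multiplicity correction.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: AR1
baselines (φ = 0.9 at 1-min sampling; MAP 60 ± 5 mmHg, SctO2 70 ± 3 %),
optional quadratic drifts, Poisson spike artifacts, configurable gaps, and
— only inside ground-truth "impaired" epochs — a zero-phase band-pass
(Butterworth, 8–32 min) copy of the MAP fluctuation mixed into SctO2 at a
variance fraction `coupling_strength`, optionally rotated in analytic
phase. The variance-fraction parameterization gives an analytically
controllable coherence target in exactly the band the index reads; it is
not a hemodynamic forward model. What passing tests therefore show is that
the pipeline detects band-limited in-phase coupling at the right times,
scales and phases and stays quiet under the red-noise null; they cannot
show robustness to features the generator lacks (non-Gaussian artifacts,
measurement nonlinearity of the oximeter, nonstationary φ, true
physiological transfer dynamics).

The synthetic cohort draws an impairment level u ~ U(0,1) per patient and
maps it linearly to an index (15·u, spanning the observed 0.6–15 % range)
and to a neuroimaging total (slope 12 by default) with additive Gaussian
noise clipped at zero. The default noise SD 4.2 was calibrated once so the
median index–score correlation over 100 seeds is ≈ 0.66, demonstrating the
observed effect size is recoverable end-to-end; the impairment→index half
of the chain is validated separately by the pipeline dose–response test.

## Numerical choices and problem sizes

- Scale grid s₀ = 2 min, dj = 1/12, 61 scales to period ≈ 66 min.
- R² is clipped into [0,1] only to absorb float error ≤ 1e−10; a larger
  excursion raises, since it would indicate a smoothing bug. Points with
  vanishing smoothed auto-power get R² = 0.
- Quantiles are plain empirical (`numpy.quantile` linear interpolation);
  ensembles below 30 surrogates are refused because a 95th percentile from
  fewer values no longer honours α.
- All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` spawning, one child per segment; reports are
  byte-identical under a fixed seed.
- Test and validation runs use 1440-min (one-day) records and, where an
  ensemble is only instrumental (dose–response, phase-separation checks),
  40–60 surrogates; the published-threshold checks use the full n = 300.
  These sizes keep the whole validation suite in the minutes range while
  leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The AR1 null assumes Gaussian innovations; heavy-tailed innovations
  would thicken the null R² tail slightly.
- The smallest scale (2 min = 2Δt) sits at the Nyquist edge, where any
  discrete wavelet transform is convention-dependent; the index band
  (8–32 min) is far from it.
- The per-category severity definitions and weight factors of the imaging
  score are external to this package; only the printed totals and category
  boundaries are reproduced.
- The printed significance "p < 0.0001" of the cohort correlation is not
  reproducible from the published per-patient values, which give
  p ≈ 3 × 10⁻⁴ (two-sided, n = 25); the package reports the computed value.
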