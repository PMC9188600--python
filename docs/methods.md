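# Methods

This note documents the models, numerical choices and known limitations of
`phonemark`. It is written for a maintainer or reviewer who wants to know
*why* the pipeline is built the way it is, not just what it computes.

## Analysis front-end

Every recording is reduced to a 0.5 s window taken from the temporal
center (sustained vowels are treated as stationary; the center avoids
onset/offset transients — whether the original front-end this mirrors
trimmed from onset or center is not documented, so center was chosen and
is noted as a choice, not a fact). The window is then band-pass filtered
with a causal 4th-order Butterworth between 50 Hz and 4 kHz. A zero-phase
variant (`zero_phase=True`) exists but defaults off, since a plain IIR
application is the conventional reading. No resampling is performed at
this stage; all analyses are parameterized in seconds and Hz, so 44.1 kHz
and 48 kHz material behaves identically.

One deliberate deviation: **formant analysis runs on the trimmed but
unfiltered segment.** A 4 kHz band edge sits inside the 5.5 kHz formant
analysis band; filtering first plants a spectral cliff that the
autoregressive fit latches onto (a spurious ~4.5 kHz pole) and makes any
F4 above 4 kHz unmeasurable. The intensity and glottal analyses, which
live well inside the band, use the filtered signal.

## Intensity

Framewise energy averaging: `I = 10 log₁₀(mean s² / p₀²)`, `p₀ = 2·10⁻⁵`,
in half-open 32 ms frames every 8 ms (≥ 2 pitch periods at the 75 Hz pitch
floor). Only the SD and range of the contour are used as features; both
are invariant to the dB reference, so the choice of `p₀` is cosmetic.
All-zero frames are floored at −100 dB with a logged warning.

## Glottal-cycle detection

Pulse marking is autocorrelation pitch tracking plus cycle-peak
refinement; it is validated by recovery tests on synthetic vowels with
known pulse times rather than by matching any external analyzer
bit-for-bit.

- Framewise period estimation: 40 ms frames, 75 % overlap, lags restricted
  to the configured pitch range (default 75–500 Hz). The autocorrelation is
  Pearson-normalized per lag (both windows mean-removed, normalized by
  their norms) — a biased FFT autocorrelation carries a `(1 − l/N)` taper
  that is ruinous at 10 ms lags in a 40 ms frame and would wreck the HNR
  scale, which lives on `r₀` near 1.
- A frame is voiced when its peak correlation reaches 0.45; fewer than a
  quarter of frames voiced raises an unvoiced-signal error (white noise
  fails here).
- Subharmonic/octave guard, two layers: within a frame, among local maxima
  within 87 % of the global peak the *shortest* lag wins (a lag of 2T
  correlates almost as well as T); across frames, candidates deviating
  from the running median period by more than the 0.7–1.43× band are
  re-searched near the median.
- Pulse times are marched from the strongest waveform peak, one predicted
  period at a time, each refined to the local waveform maximum (polarity
  fixed by the dominant extreme). Cycles whose period deviates > 30 % from
  a local 9-cycle median are discarded iteratively.
- Cycle amplitude `Aᵢ` is the peak absolute sample in a ±0.2-period window
  *centered on the mark*. A window spanning the whole cycle would
  sometimes capture the build-up of the next pulse and mix neighboring
  amplitudes, which measurably compresses shimmer.

Jitter, shimmer and pitch SD are computed exactly as the formulas in the
README state (sample SD, n−1 denominator, log base 10).

## Harmonicity

Per 40 ms frame, the highest normalized-autocorrelation peak at a lag
within ±20 % of the frame's local period gives `r₀`. Frame values are
averaged **in the r₀ domain** and converted once:
`HNR = 10 log₁₀(r₀/(1−r₀))`, `NHR = 1 − r₀`. Averaging per-frame dB values
instead would break the exact `NHR = 1/(1+10^(HNR/10))` identity the test
suite asserts at 1e−12. Whether the reference analysis computed
harmonicity on the whole segment or frame-averaged is ambiguous;
frame-averaging is standard practice and is the documented choice here.
Frames with `r₀ ∉ (0, 1)` are excluded; if all frames are excluded the
signal is reported as degenerate.

## Formants and vocal tract length

The segment is resampled to 11 kHz (twice the 5.5 kHz ceiling),
pre-emphasized with `1 − a z⁻¹`, `a = exp(−2π·50/fs)`, cut into 25 ms
Gaussian-windowed frames every 6.25 ms, and fit with a Burg AR model
(coefficients via `statsmodels`). Complex-pole angles give candidate
frequencies, `−ln|r|·fs/π` their bandwidths; candidates below 90 Hz, above
the ceiling, or wider than 400 Hz are discarded and the lowest four kept
in order.

- **AR order 12**, i.e. two poles per expected resonance in the band plus
  one spare pair. The spare pair absorbs residual source/noise spectral
  shaping; with order 10 the fit cannot simultaneously carry four
  formants and the source envelope, and loses F4 when it sits high
  (≈ 4.9 kHz for a 12 cm tract). Order is configurable.
- The highest formant may legitimately fail the bandwidth screen in
  individual frames, so per-frame absences are allowed; only a majority of
  frames missing two or more formants raises a formant-failure error
  (white noise fails this way).
- VTL is computed from the per-recording *mean* formants (not framewise
  and then averaged): `VTL(Fᵢ) = (2i−1)·33,500/(4Fᵢ)` cm, four values per
  recording.

Recovery on synthetic tubes of 12–19 cm is within ±2.5 % per formant
index (the acceptance script recomputes this), with one caveat: when F1
sits exactly on a low harmonic of f0, LPC's harmonic attraction can bias
F1 by a few percent — a known property of all-pole fits on voiced speech,
not specific to this implementation.

## Statistics

- Anderson–Darling A² with estimated mean/variance, small-sample
  correction `A*² = A²(1 + 0.75/n + 2.25/n²)`, 5 % rejection at 0.752.
  The statistic is computed from the log-CDF form directly and is checked
  against an independent library implementation in the tests.
- Mann–Whitney U, two-sided: exact null when `n_x + n_y ≤ 12` with no
  ties, otherwise normal approximation with tie and continuity
  corrections. The exact branch is verified against full enumeration of
  all rank assignments.
- Effect size is **Glass's Δ = (mean_control − mean_disease)/SD_control**.
  The source tables this mirrors do not print their effect-size formula;
  Glass's Δ with the control SD reproduces the printed values where
  Cohen's d does not, and that reverse-identification is the basis for
  the choice. Positive Δ means controls are higher (so perturbation
  features, elevated in disease, come out negative).
- Demographic tables are reproduced with pooled two-sample t-tests
  (df = n₁+n₂−2) and summary-reconstructed one-way ANOVA. Equal group
  sizes make pooled and Welch t identical here, which is why pooled was
  chosen. One known inconsistency in the source demographic table: a
  female-PD age SD printed as 72.66 is incompatible with the printed ANOVA
  p = 0.966 (it is plausibly 7.66); that ANOVA row is therefore not used
  as a reproduction target.
- No multiple-testing correction is applied, mirroring the analysis this
  package re-implements; the stats table reports raw p-values.

## Classification

- Relief-F with k = 10 nearest hits/misses on min-max-scaled features,
  weight ties broken by feature name for determinism. Implemented from the
  update rule directly (no library implementation exists in the stack) and
  checked against a literal hand transcription on small instances.
- Gaussian-kernel SVM (`sklearn.svm.SVC`), `C = 1`, `gamma = "scale"`
  (= 1/(n_features·Var)). The reference analysis states the kernel but no
  hyperparameters; results on real data will vary with them, so both are
  exposed in `RunConfig`.
- Leave-one-out is per *recording* (each repetition is one sample), with
  z-scoring recomputed from each training fold only — the no-leakage test
  plants a label-copy feature and verifies that removing it returns the
  table to chance. Leave-one-subject-out would be methodologically safer
  against speaker memorization and is noted as such; per-recording was
  kept to mirror the granularity of the reported confusion totals.
- Phoneme combination joins tables on (subject, repetition) with
  phoneme-prefixed feature names; rows missing any phoneme are dropped
  with a logged count.

## Synthetic vowel generator

Source–filter synthesis with exact, self-consistent ground truth:

- **Pulse train.** Periods `Tᵢ = T₀(1 + s·zᵢ)` with `z` truncated standard
  normal (±3σ). The scale `s` is solved in closed form so the realized
  relative jitter of the emitted sequence equals the target exactly
  (`jitter_rel = s·a/(1+s·b)` for draw constants `a, b`); amplitudes are
  calibrated the same way for shimmer. `SynthTruth` stores the pulse
  sequence as rendered on the sample grid, and its jitter/shimmer fields
  are recomputed from that emitted sequence, so extraction can in
  principle match them exactly.
- **Source.** One differentiated Rosenberg pulse per cycle, opening phase
  40 % of the cycle, closing time fixed at 0.08 of the *mean* cycle. Two
  details matter and were found the hard way: the closure spike is
  anchored to the grid pulse time (anchoring the pulse onset would smear
  the period sequence by ~half, because the closure sits a
  period-dependent fraction after the onset), and the closing time must
  not scale with the individual period (the spike width sets the
  excitation of the upper formants, so period-proportional closure
  converts jitter into spurious shimmer). The derivative is sampled
  analytically at global sample positions; the closure sample is exactly
  −Aᵢ.
- **Tract.** Cascade of second-order all-pole resonators, either at
  explicit formants or at the odd quarter-wavelength series of a uniform
  closed tube; default bandwidth 80 Hz per formant.
- **Noise.** White Gaussian, band-limited to 50 Hz–4 kHz, then shaped by
  the same resonator cascade — aspiration noise enters at the glottis and
  shares the tract envelope. Flat (unshaped) noise would bury the upper
  formants under a noise floor no real voice has. The level is set
  relative to the harmonic RMS (`noise_db`), which controls the extracted
  HNR monotonically.
- **Drift and normalization.** dB-linear gain ramp spanning
  `intensity_drift_db` peak-to-peak across the recording; final peak
  normalization to 0.95.

Per-class presets shift jitter, shimmer, noise and drift in the disease
direction (PD higher perturbation and noise), with magnitudes near the
published group means of those quantities; they are not claimed to
reproduce any printed table numerically. Subject-level lognormal scatter
(σ ≈ 0.35) makes the classes overlap the way real cohorts do. The vowel
formant targets are per-phoneme constants, identical across classes — so
in synthetic cohorts the class signal lives in the intensity/glottal
features, and the vocal-tract features act as null features. This is the
opposite of the finding on real PD voices (where VTL separated best), and
it is intentional: the generator validates the *measurement machinery*,
not the clinical effect.

What the generator does not emulate: articulatory dynamics, vocal tremor
(low-frequency f0 modulation), diplophonia/subharmonics, room acoustics
and microphone coloration, and any dependence of tract shape on disease
status. Passing tests therefore demonstrate correct measurement and
honest statistics on a controlled signal model — not clinical performance
on real voices.

## Validation regimes and problem sizes

Parameter-recovery checks (jitter/shimmer grid 3×2, five seeds per cell;
tract lengths 12/14/16.75/19 cm, three seeds) run 1 s vowels at 44.1 kHz.
The jitter/shimmer grid runs in the low-aperiodicity regime
(`noise_db = −60`): additive noise puts a floor of a few percent under the
peak-amplitude measurement, which is a property of peak-based shimmer on
noisy signals generally, and is assessed separately (the noise series
checks HNR monotonicity over −40…−10 dB). VTL recovery runs at a
disease-like operating point (jitter 0.008, shimmer 0.05, noise −18 dB).
Classification sanity uses 20+20-sample clusters (10σ separation for the
perfect-separation check, 3σ with permuted labels for the chance check)
and 100-sample instances for Relief-F ranking. The end-to-end synthetic
cohort is 20 recordings per class, one vowel. These sizes were chosen so
each recovery claim is a mean over enough seeds to be stable while the
whole suite stays fast to iterate on.

## Known limitations

- Pulse detection assumes one dominant excitation per cycle; creaky or
  diplophonic phonation would defeat the octave guards.
- Shimmer measured from waveform peaks has a noise floor of a few percent
  under realistic additive noise; comparisons across groups remain valid
  (the floor is common to both), but absolute values at very low shimmer
  are inflated.
- LPC formant estimates inherit harmonic attraction at high f0 and
  low F1.
- The SVM operating point (C, γ) is fixed, not tuned; reported accuracies
  on real data would be sensitive to it.
- Exact Mann–Whitney is limited to pooled n ≤ 12 without ties; beyond
  that the corrected normal approximation is used.
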