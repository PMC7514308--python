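# Methods

## Ordinal symbolization

A series is embedded as vectors `(x[s−(d−1)τ], …, x[s−τ], x[s])` and each
vector mapped to the permutation of time offsets ordering its values
descendingly. Ties are resolved by temporal position with the *earlier*
sample (larger offset) first, so a constant vector maps deterministically
to `(d−1, …, 1, 0)`; equivalently, the symbol is the lexicographically
largest permutation satisfying the weak descending chain. Patterns are
stored by lexicographic rank (a Lehmer-code bijection), so distributions
index into a dense length-`d!` vector.

Vectors containing NaN are skipped and counted separately rather than
imputed, keeping the distribution normalized over valid vectors. Long
recordings are symbolized in overlapping chunks (default 10^6 samples,
overlap `(d−1)τ`), so hour-long 48 kHz files stream in bounded memory.
A warning (not an error) is raised when `N < 100·d!`, the regime where the
plug-in entropy estimator is visibly biased.

Defaults are `d = 6`, `τ = 1`. Dimensions 3–7 are practical: below 3 the
pattern alphabet is trivial; above 7 the `d!` states demand series lengths
rarely available per analysis window. `τ` stays at 1 for detection: the
discriminating information is at the shortest timescale, where chorus
periodicity reorders neighboring samples but low-frequency noise cannot.

## Quantifiers

All entropies are in nats. `H = S[P]/ln d!`. The disequilibrium
normalization `Q_0` is the exact closed form of the Jensen–Shannon
divergence between a delta and the uniform distribution,
`J_max = −½[((M+1)/M)·ln(M+1) − 2·ln 2M + ln M]`, not a numerical
maximization. The entropy estimator is the plug-in (no finite-sample bias
correction): the white-noise landmark `H ≈ 0.93` is a *finite-length*
value (length ≈ 900 at d = 6); longer noise drifts toward `H → 1, C → 0`,
which is why the reference computation fixes the length rather than
guessing an asymptote. Audio is analyzed at full resolution; no decimation
is applied by default.

The `C_min` boundary of the C-H plane comes from the one-parameter family
`{p, (1−p)/(M−1), …}` with `p ∈ [1/M, 1]`; `C_max` is the upper envelope
over the families with `n = 0…M−2` empty states, one free component
`p ∈ [0, 1/(M−n)]` and the remaining mass split equally. Both are sampled
on a configurable grid (default 2000 points; quadratic spacing in the free
parameter to resolve the `p → 0` entropy singularity), accumulated into a
uniform H grid and linearly interpolated; containment checks therefore
carry an interpolation tolerance (10⁻³ suffices for d = 4 at the default
grid). Envelope construction is refused above `M = 5·10⁴` (d ≥ 9), where
per-family sampling becomes meaningless at any practical grid.

## Spectral levels

Calibration is a single end-to-end sensitivity `S` dB re 1 µPa (default
−164.5): pressure = sample · 10^(−S/20). PSDs are Welch estimates (Hann
window, 50 % overlap, one-sided, density scaling, no detrending) on 1-s
segments, arithmetically averaged in linear power to the analysis-window
resolution (60 s in the field configuration). Band SPL is
`10·log10(Σ PSD·Δf)` over bins whose centers lie inside the band, both
edges inclusive. "Mean (RMS)" statistics average linear power before
converting to dB (an option averages dB instead); median and the 95th
percentile are order statistics of the dB series. Digital silence floors
at −200 dB with a warning instead of propagating −∞.

## Acoustic indices

ACI, ADI and BI use a Hamming-window, zero-overlap magnitude spectrogram
(FFT 2048 at field rates; 256 for the compressed synthetic scenes, keeping
~31 Hz resolution against the field's ~39 Hz). ACI sums
`Σ|ΔI|/ΣI` per frequency bin within 60-s clusters and totals (not
averages) over bins and clusters; bins below a 10⁻¹⁰-relative intensity
floor (−200 dB) are treated as silent so numerically-zero leakage cannot
contribute spurious variation. ADI thresholds the spectrogram at −50 dB
relative to the recording maximum and takes the Shannon index of
per-band occupancies over the 17 full 200-Hz bands below 3500 Hz (the
3400–3500 Hz remainder is discarded; both the band width and cut are
configurable). BI averages the dB spectrum over the recording, subtracts
the in-band (10–3500 Hz) minimum and sums the offset curve in bin units.

## Detection and evaluation

Indices are min–max normalized per deployment series (the scope can be
narrowed to per-day, but a single scope must be used before thresholding).
Detection is strict: `> 0.5` for C/ACI/ADI/BI, `< 0.5` for H; exactly 0.5
is never a detection. The joint C-H detector is the union of the H and C
detections — both coordinates flag the same movement toward the
deterministic corner of the plane, and the union recovers chorus hours
where only one quantifier clears its threshold — while the five per-index
confusion matrices are always reported separately. Correlations are
standard two-sided Pearson tests, overall and within Dawn (00–05),
Dusk (18–23) and Midday (06–17) clock groups, against both the
chorus-masked 500–2500 Hz SPL (kept in chorus hours, zero elsewhere) and
the raw 50–200 Hz noise-band SPL.

## Synthetic soundscape

The simulator renders time-compressed, labeled scenes: by default one
"hour" is 10 s of audio at 8 kHz, so a 24-h day is 1.92 M samples and a
six-day deployment analyzes in under a minute on one core. The detector is
rate-agnostic, and the index/SPL parameterizations carry a scaled variant
for the compressed rate.

Components (additive, rendered in µPa, then converted to calibrated
samples):

- **Chorus** — per caller, a jittered 8 s⁻¹ train of 40-ms exponentially
  damped sinusoid bursts with center frequency uniform in 800–1600 Hz,
  band-limited to 500–2500 Hz. Intensity scales the *number of callers*
  (150 at full intensity) with level following `113 + 10·log10(e)` dB:
  mild choruses are sparse scatters of distinct calls, intense ones merge
  into a near-continuous roar. This is what makes ACI rise for sparse
  chorusing yet fall back to its noise baseline for dense chorusing, while
  H/C respond monotonically. The diel envelope spans 00–05 (peak 03:00)
  and 17–22 (peak 19:00).
- **Vessel passages** — harmonic stacks (fundamental 25–60 Hz, harmonics
  to 200 Hz, 1/k amplitudes) under a Gaussian passage envelope with slow
  amplitude modulation; peak level 112 dB.
- **Sediment transport** — Poisson bursts (2 s⁻¹ while active, 150 ms) of
  10–70 Hz band-limited noise, 108 dB over active periods.
- **Background** — colored Gaussian noise, flat below 100 Hz and
  `f^(−1)` above, 95 dB broadband.

Per-hour truth records chorus presence and intensity, the realized
chorus-component band level, vessel passage counts and the sediment duty
fraction. Four canonical case days isolate regimes (intense chorus +
sediment; mild chorus + vessel + sediment; mild dawn chorus + 18 vessel
passages; no chorus with continual sediment), and a deployment generator
renders multi-day scenes with day-varying chorus intensity for
correlation analyses.

What the generator does *not* emulate: species-accurate call waveforms,
propagation/multipath, dolphin whistles, pile driving, and the slow
spectral weather of real sites. Passing tests therefore demonstrate that
the quantifiers respond to *band-limited quasi-periodicity against noise*
— the mechanism the method relies on — not that field accuracies will
match the synthetic ones. One known divergence: the synthetic background
occupies all 17 ADI bands above the −50 dB relative threshold, so ADI
saturates near ln 17 ≈ 2.83 on quiet hours and mostly responds (downward)
to loud narrowband events; on real recordings ADI can track choruses more
closely. The ADI occupancy semantics themselves are tested on constructed
spectrograms.

## Numerical choices and degenerate inputs

- Constant index series normalize to all zeros (flagged) rather than NaN.
- Zero-variance series report `r = NaN` instead of raising.
- `0·ln 0 = 0` throughout; probability vectors must sum to 1 within 10⁻⁹.
- Welch segments shorter than one window, bands outside Nyquist, empty
  band masks, non-binary confusion inputs and mismatched window ids all
  raise `ValueError` early.
- Scenes are bit-reproducible for a fixed config and seed (one
  `numpy.random.Generator` drives all components in a fixed order).

## Limitations

- The 0.5 threshold presumes each deployment contains both chorusing and
  quiet hours; a deployment that is all-chorus or all-quiet degrades to
  the degenerate normalization case.
- Accuracy comparisons between detectors on synthetic scenes depend on the
  programmed interference mixture; they reproduce orderings, not field
  percentages.
- p-values for the strongly negative H correlations are reported two-sided
  (values near 1 under a one-sided convention are not replicated).
- Weighted/multiscale permutation-entropy variants, other acoustic indices
  (NDSI, AEI, …), ROC threshold sweeps and multiple-testing corrections
  are out of scope.
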