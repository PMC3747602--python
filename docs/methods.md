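# Methods

This note describes, in the package's own terms, what `sdppg` computes
and the numerical conventions it uses.

## Background and goal

The second derivative of a finger photoplethysmogram (SDPPG, also called
the acceleration plethysmogram) exhibits five alternating systolic
extrema, the waves a (maximum), b (minimum), c (maximum), d (minimum) and
e (maximum). Their normalized amplitudes summarize the shape of the pulse
wave; the ageing index

    AGI = (b − c − d − e) / a

increases with arterial stiffness and vascular age. Measured beat by
beat, AGI scatters strongly because differentiating twice amplifies
broadband noise and because heartbeats vary in duration, which moves the
pulse harmonics relative to any fixed filter. The pipeline in this
package reduces that scatter by time-normalizing every beat, filtering on
the normalized grid with a sharp equiripple low-pass, and ensemble
averaging before the waves are read.

## Processing pipeline

All processing happens at the canonical rate of 1 kHz; `read_signal`
resamples other rates on ingestion (cubic spline).

1. **Band separation** (`bandpass_ppg`). A 30 Hz low-pass (Hamming
   window design, order 500) removes wideband noise; a 0.5 Hz high-pass
   (order 4000) removes the DC level and baseline drift. Both filters are
   linear phase and are applied forward-only with exact group-delay
   compensation; the first and last `order/2` samples are discarded
   rather than padded, and the signal's `t0` is advanced accordingly, so
   no fabricated transients enter the analysis and all stages stay on one
   timeline.
2. **Noise-robust differentiation** (`snrd`). The second and fourth
   derivatives are computed by repeated application of a 5-point smooth
   noise-robust differentiator, an antisymmetric FIR kernel

       f'(t) ≈ [2(f₊₁ − f₋₁) + (f₊₂ − f₋₂)] / (8h)

   that is exact on quadratics, matches the ideal differentiator within
   1 % up to 15 Hz at 1 kHz, and has an exactly zero response at the
   Nyquist frequency. Longer odd-length members of the same family are
   available (`snrd_kernel(length)`).
3. **Beat segmentation** (`segment_beats`). Steepest-rise points are
   local maxima of the first derivative with a 0.3 s refractory period
   and a height threshold at half the median rise peak; each foot is the
   signal minimum in the 0.35 s window before a rise. Feet and rises are
   localized on a 10 Hz low-passed copy so that noise on the nearly flat
   diastolic tail cannot move the foot; amplitudes are never read from
   the smoothed copy. Beats outside 0.3–2.0 s are rejected.
4. **Time normalization** (`normalize_recurrence`). Each foot-to-foot
   recurrence, with surrounding context, is cubic-spline resampled so the
   beat spans exactly 1000 samples (1 s at 1 kHz). This places the pulse
   fundamental at 1 Hz and all harmonics at integer frequencies,
   independent of the original beat duration. Derivatives are resampled
   as-is: the `duration^k` scale factor the k-th derivative would acquire
   is common to the whole beat and cancels in every normalized ratio and
   in AGI.
5. **Equiripple harmonic filtering** (`design_pm_lowpass`). On the
   normalized grid, an equiripple (minimax) low-pass with passband edge
   `f_e`, a 1 Hz transition band and 0.001 ripples in both bands keeps
   the fundamental plus `floor(f_e) − 1` harmonics and suppresses
   everything above. The tap count starts at the Herrmann–Rabiner order
   estimate,

       N ≈ D∞(δ₁, δ₂)/ΔF − f(δ₁, δ₂)·ΔF,

   which gives 3255 for δ₁ = δ₂ = 0.001 and ΔF = 1/1000 (truncated
   toward zero), and is increased until the realized deviation measured
   on a dense frequency grid meets the ripple specification. An even tap
   count is used because the exchange algorithm converges reliably there
   for this specification; the resulting half-sample group delay is
   removed by spline re-interpolation, so the filter is effectively
   zero-phase on the sample grid. Filtering happens per beat with real
   signal context on both sides (trim, not pad).
6. **Alignment and averaging** (`align_and_average`). Each normalized
   beat is aligned at the sub-sample time where its PPG crosses 50 % of
   the foot-to-peak rise; the ensemble average of PPG, SDPPG and fourth
   derivative is formed on the intersection of the aligned supports, with
   the reference at τ = 0.
7. **Wave detection** (`detect_waves`). Zero crossings of the fourth
   derivative bracket the SDPPG extrema: between two consecutive
   crossings the SDPPG has at most one extremum. Wave a is the dominant
   SDPPG maximum inside the systolic search window (default
   [−0.15 s, +0.45 s] around the alignment reference); b–e are then the
   alternating min/max/min/max in the successive inter-crossing
   intervals, refined to sub-sample precision with a three-point
   parabola. If an expected c or d extremum does not exist (a monotone
   limb with only an inflection), the wave is placed at the fourth-
   derivative extremum of its interval and flagged in
   `WaveFeatures.fallback`. The polarity pattern (a > 0, b < 0, strictly
   ordered times) is enforced; violations raise a `DetectionError` that
   reports how many waves were resolved.

`analyze_signal` runs the chain end to end on the first `n_beats`
(default 15) normalizable recurrences, detects waves both on the averaged
waveform and on every individual normalized beat, and reports the
beat-to-beat dispersion of each statistic.

## Dispersion statistics and the edge-frequency sweep

The per-subject dispersion of a statistic x (AGI, b/a, …, or a wave time)
is measured about the averaged-waveform value, not the sample mean:

    SD = sqrt( Σᵢ (x_beat(i) − x_avg)² / (n − 1) ),          (1)

and the group dispersion is the arithmetic mean of per-subject SDs:

    SD_avg = (1/m) Σₖ SD(k).                                  (2)

Wave-time dispersions are reported in milliseconds. Beats whose detection
fails are excluded with n reduced; a statistic with fewer than two
surviving beats is NaN.

`edge_frequency_sweep` repeats the full pipeline over a grid of passband
edges (default 4–14 Hz, step 1) and reports Eq. (2) per edge and
statistic. The dispersion is U-shaped in the edge frequency: below about
6 Hz the harmonics that form the c–e waves are removed, so detection
degenerates to the fallback and scatters; above it, each extra harmonic
admits noise that the differentiators amplify. The minimum sits at 6 Hz —
the fundamental plus five harmonics — which is the package default.

## Cohort statistics

`fit_agi_age` fits AGI = slope·age + intercept within the healthy group
by ordinary least squares (equivalently, the identity-link Gaussian
generalized linear model) and reports the Pearson correlation and
residual SD. `bland_altman_vs_model` summarizes per-subject differences
from the fitted line; `compare_groups` applies Welch's unequal-variance
two-sample t-test (two-sided, Welch–Satterthwaite degrees of freedom) to
the healthy and patient difference distributions. A paired test is not
applicable because the groups are independent and differently sized.

## Synthetic generator

`simulate` provides the ground truth for all tests and examples. One beat
is a sum of five Gaussians (systolic onset, main systolic peak,
late-systolic shoulder, dicrotic wave, diastolic tail) on the unit
period, with an analytic Fourier series: for a component with amplitude
A, center μ and width σ (period fractions), the n-th one-sided
coefficient is

    cₙ = A σ √(2π) · exp(−2π²σ²n²) · exp(−2πi n μ).

A stiffness parameter s ∈ [0, 1] interpolates the component parameters
between a compliant endpoint (wavy, pronounced c–e waves, AGI −1.74 at
the 6 Hz edge) and a stiff endpoint (broad, near-triangular, AGI +0.99).
The family was chosen so the SDPPG harmonic spectrum peaks near the 4th
harmonic and decays through the 8th–10th, i.e. the waves are genuinely
formed by the fundamental and roughly five harmonics, matching the
operating conditions the pipeline is designed for, and so that the clean
template's AGI is strictly monotone in s, which lets `stiffness_for_agi`
invert it numerically (Brent's method) to hit a target index.

Ground-truth annotation is computed independently of the pipeline: the
Fourier series is truncated at the last harmonic inside the passband
(ideal brick-wall filtering on the normalized base), evaluated on an
8192-point grid, and the waves are located by direct search between
fourth-derivative zero crossings with the same conventions the detector
documents. Recordings are assembled from period-jittered beats (each beat
is the template traversed at a constant rate over its own jittered
period), plus sinusoidal baseline drift, optional powerline interference
and white noise; `noise_rel_for_snr_db` converts an AC signal-to-noise
ratio in dB into the generator's relative noise amplitude. A single
seeded generator fixes every recording bit for bit; cohort subjects
receive seeds drawn from one master generator.

`generate_cohort` draws ages uniformly, assigns target AGIs from a linear
age model plus Gaussian residual scatter (patients additionally offset
upward), and optionally inverts the template family per subject. Targets
outside the family's attainable range raise an error naming the range.

## Limitations

- The per-beat "baseline" mode is a simplified conventional comparator
  (band-pass and differentiation only), intended for dispersion
  comparisons, not as a faithful reimplementation of any particular
  published per-beat method.
- The generator is phenomenological: it reproduces the morphology and
  statistical structure the algorithm assumes (quasi-periodicity, drift,
  broadband noise), not hemodynamics.
- Real-data headline values (specific dispersion magnitudes, regression
  coefficients of human cohorts) depend on the instrument and population;
  the package's tests verify properties and recoveries on synthetic data.
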