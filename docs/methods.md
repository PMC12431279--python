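# Methods

This note documents the model, the numerical choices, the tunable
parameters, and the known limits of the implementation.  Heart rate (HR)
is expressed in Hz throughout (ν = 1/T); multiply by 60 for bpm.

## Wavelet transform and normalization

The analysis surface is the discretized Morlet continuous wavelet
transform

    W(f, t0) = f * sum_t x(t) * conj(psi(f * (t - t0))) * dt
    psi(eta) = pi**(-1/4) * exp(2j*pi*eta) * exp(-eta**2 / 2)
    E(f, t0) = |W(f, t0)|**2

with dt the sampling period.  Because the carrier completes one cycle per
unit of eta, the scale parameter f is read directly as pseudo-frequency in
Hz with no center-frequency correction.

**Normalization.**  The prefactor is the plain frequency `f`.  After the
change of variable u = f(t − t0), the integral contributes a factor 1/f,
so with this prefactor |W(f, ·)| for a pure tone at f₀ is a Gaussian in
(f₀/f − 1) with its maximum exactly at f = f₀.  An L²-style `sqrt(f)`
prefactor would leave a net f^(−1/2) trend that biases the energy argmax
low by 1/(2·(2π)²) ≈ 1.3% — two grid steps at the default resolution —
so the frequency-unbiased normalization is used.  The choice affects only
this bias; all downstream quantities are ratios or argmax positions.

**Truncation and edges.**  The infinite sum is truncated at |eta| ≤ 5,
where the Gaussian envelope is below 4·10⁻⁶; the truncated fast
(FFT-convolution) path agrees with the direct sum to ~10⁻¹² relative.
Cells whose truncated support crosses a record edge (a cone of influence
of half-width 5/f seconds) are flagged and excluded from ridge selection;
the first and last stretches of the output are therefore gap-filled and
marked as such.

**Grid.**  Linear frequency spacing, default step 0.005 Hz.  The analysis
bands are 0.4–0.8 Hz wide, so the default gives ~80–160 bins per band;
the ridge quantization error (step/√12 ≈ 0.0014 Hz RMS) is negligible
against the smoothing effects below.  Time is decimated tenfold (output
rate fs/10, i.e. 25 Hz at fs = 250 Hz).  All arithmetic is double
precision.

## Skeleton and pattern linking

At each decimated time the skeleton is the set of strict interior local
maxima of E(·, t) on the grid (E[i−1] < E[i] > E[i+1]); grid endpoints
are never reported, and on an exact floating-point tie plateau the
leftmost cell counts.  At most `max_skeletons = 25` maxima are kept per
time, largest energies first.

Skeleton points at consecutive times are chained into oscillatory
patterns when their frequencies differ by at most `epsilon = 0.04` Hz
(ten sampling periods of a 250 Hz recording, read on the frequency axis).
When several (pattern head, new point) pairs are within epsilon, they are
matched greedily by ascending frequency distance, ties toward the lower
frequency; each head extends at most once and each point is used at most
once, so the result is deterministic and every skeleton point belongs to
exactly one pattern.  A missed frame terminates a pattern permanently —
patterns never merge, split, or bridge gaps.  The epsilon comparison
carries a 10⁻¹² absolute slack because grid arithmetic can produce
differences a few ulp above the nominal tolerance.

## Ridge selection and admissibility

Within an analysis band the reported frequency sc(t) at each time is the
in-band, non-edge point of the admissible pattern with the greatest
cumulative in-band energy among the patterns covering that time; ties go
to the earlier-born pattern.  Admissibility imposes two conditions, both
chosen from failure analysis on synthetic ground truth:

* **Energy floor.**  A pattern must accumulate at least 1% of the largest
  cumulative in-band energy over all patterns.  Noise-born chains live
  for a few frames at ≤0.1% of the dominant chain's energy, while genuine
  fragments of the cardiac component (e.g. a chain broken by an artifact
  burst) retain ≥2.5%; without the floor, a one-point noise chain can
  supply the ridge wherever the dominant chain happens to be broken.
* **Median in band.**  The pattern's median frequency must lie inside the
  band.  An energetic chain tracking a *different* component can drift
  across the band edge for a few frames; its cumulative energy would
  otherwise outrank the true in-band chain and clamp the ridge to the
  band edge.

Times with no admissible in-band point are gaps.  Gaps are filled by
linear interpolation (nearest value at the record ends) and recorded in
the output's gap mask; reconciliation (below) replaces fundamental-band
gap samples with the harmonic-band estimate where that band has a ridge.

## Pipeline

1. **Fundamental frequency.**  Fmain is the largest Hann-windowed FFT
   amplitude peak in the search range (default [0.5, 2.0] Hz) over the
   whole record.  Because QRS spectra are harmonic-rich, the raw maximum
   can fall on the second harmonic: if a peak of ≥40% relative amplitude
   exists near half the chosen frequency, the subharmonic wins.  A
   constant or peak-free spectrum is an error.  Records under 60 s
   trigger a warning.
2. **Bands.**  Fundamental [Fmain(1−w), Fmain(1+w)] and harmonic
   [2Fmain(1−w), 2Fmain(1+w)] with w = 0.2, i.e. [0.8, 1.2] and
   [1.6, 2.4] Hz at Fmain = 1.  One CWT surface covering both bands
   (padded by two grid steps so band-edge maxima remain interior) serves
   both ridges.
3. **Two estimates.**  The harmonic-band ridge divided by two is an
   independent estimate of the same rate.  Their per-time difference is
   reported in the diagnostics; `reconcile` merges them (fundamental
   preferred, harmonic substitution in fundamental gaps, interpolation
   when both are gapped) with per-sample provenance.

## R-peak baseline

The comparison baseline is the classical derivative/energy detector:
band-pass 5–15 Hz (0.5–8 Hz for PPG), differentiate, square, 150 ms
moving-window integration, adaptive dual thresholds with exponential
averaging of signal/noise peak levels, a 0.25 s refractory period, and a
search-back pass at 1.66× the running mean RR for missed beats; the final
peak position is the raw-signal maximum within ±100 ms.  Beat-to-beat
rate values ν = 1/T are placed at interval midpoints and transferred to
an equidistant grid by linear interpolation (extrapolation is refused).
This recipe is a representative of the classical contour-analysis family,
not a re-implementation of any specific published detector; agreement
with it is measured, not assumed.

## Agreement statistics and spectral indices

Two series with different native rates are compared after linear
resampling onto the finer grid restricted to the time overlap.  Summary
statistics are the arithmetic mean and the sample SD (n−1); the pairwise
difference statistic is the mean absolute pointwise difference.
Bland–Altman limits of agreement are mean(d) ± 1.96·SD(d), with standard
errors SD/√n for the mean and SD·√(1/n + 1.96²/(2(n−1))) for each limit;
the percentage of differences outside the limits is reported (≈5% for
Gaussian differences by construction).  The maximum relative discrepancy
is 100·max|a−b|/b with b the reference.

Spectral indices integrate the amplitude spectrum (mean removed, Hann
taper, single full-length FFT) over VLF [0.0033, 0.04), LF [0.04, 0.15)
and HF [0.15, 0.4] Hz; the three band amplitudes are normalized by their
sum, and LF/HF is the ratio of the LF and HF amplitudes (amplitudes, not
powers).  Durations under 125 s (five periods at the LF band edge) warn;
a constant series or an empty HF band is an error.

## Synthetic generator

The generator emulates a resting adult recorded at 250 Hz.  The
instantaneous rate is

    HR(t) = mean_rate + lf_amp*sin(2*pi*lf_freq*t)
                      + hf_amp*sin(2*pi*hf_freq*t) + jitter(t)

with defaults 1.0 Hz mean, 0.03 Hz amplitudes at 0.1 Hz (LF) and 0.3 Hz
(HF), and optional jitter (white noise low-passed at 0.4 Hz so the truth
stays inside the HF band; off by default).  A configuration whose rate
can leave the physiologic range (mean − lf_amp − hf_amp ≤ 0.3 Hz) is
rejected.  Beats are placed by integrate-and-fire — beat times are the
integer crossings of ∫HR dt — so the rate ground truth is exact by
construction rather than fitted afterwards.

Morphology templates are deliberately minimal: ECG beats are a narrow
biphasic Gaussian-derivative R spike (σ = 10 ms, unit amplitude) with
P (amp 0.15, −0.18 s, σ = 35 ms) and T (amp 0.30, +0.25 s, σ = 60 ms)
Gaussian bumps; PPG beats are a smooth asymmetric pulse (fast ~0.15 s
rise, slow ~0.45 s decay, dicrotic bump), with the differentiated-PPG
variant as the scaled first difference.  Corruption adds white noise
scaled to hit the requested SNR exactly, low-passed (<0.5 Hz) baseline
wander, and 0.5–10 Hz band-limited artifact bursts of a prescribed
multiple of the clean signal's SD inside given windows, with 0.5 s cosine
ramps.  Everything is deterministic given the seed.

What the generator does **not** model: respiratory coupling physiology,
ectopy and arrhythmic morphology change, electrode-contact transients,
sensor-specific transfer functions, or pulse-transit-time variation.
Passing tests on these signals therefore demonstrate correctness of the
tracking machinery under known rate laws and severe additive corruption,
not clinical performance on pathological recordings.

## Accuracy limits of ridge tracking

Two systematic effects bound the accuracy on modulated rates, and both
are properties of the method rather than of the implementation (the
ridge-tracking residual after removing them is ~0.002 Hz):

* **Modulation smoothing.**  The Morlet envelope at frequency f has time
  width σ_t = 1/f, so rate modulation at frequency ν is recovered with
  amplitude factor ≈ exp(−(2πν·σ_t)²/2): ≈0.82 for ν = 0.1 Hz and ≈0.17
  for ν = 0.3 Hz at the 1 Hz fundamental.  The harmonic band has half
  the envelope width and recovers modulation correspondingly better
  (0.95 and 0.64), which is one reason the harmonic/2 estimate is worth
  computing.  On a ±0.1 Hz, 0.1 Hz-rate modulation this smoothing alone
  contributes ≈0.013 Hz RMS error on the fundamental ridge.
* **Template group delay.**  The ridge follows the band's energy, whose
  per-beat centroid need not coincide with the beat fiducial: in the ECG
  template the positive-area P/T bumps dominate the ~1 Hz band over the
  zero-area R spike, displacing the tracked component by a few hundred
  ms relative to R-peak-defined truth and adding an apparent lag under
  modulation (measured ≈15° at 0.1 Hz; an R-spike-only signal shows
  zero lag).  The same physics applies to real recordings, where the
  T wave and the pulse wave genuinely carry the band's energy.

Under heavy in-band corruption (band-limited artifact bursts whose
in-band energy rivals the cardiac component's), the skeleton maximum
itself can be displaced for seconds at a time; no pattern-selection rule
can recover a maximum that is not in the surface, and the harmonic
cross-check helps only where one band survives.  In the bundled burst
scenario (0 dB white noise plus two 30 s bursts at 3× signal SD) the
transient error reaches ~20–26% inside bursts while remaining below ~5%
elsewhere; the R-peak baseline under the same corruption errs by ~300%.

## Validation problem sizes

The test-suite and acceptance-script runs use: 2000 samples × 20
frequencies for the direct-sum oracle; 60 s pure tones for ridge
localization; 300 s records for chirp tracking, detector accuracy and
end-to-end defaults; 600 s records for modulated-rate tracking and the
noise/artifact scenario; n = 10⁴ for the Bland–Altman coverage check.
These sizes put quantization, edge effects and estimator variance well
below the tolerances being checked while keeping the whole suite fast.

## Known limitations

* No real-time/streaming mode; the transform, linking and band selection
  all assume the full record is available.
* Fmain is a single global estimate; records whose rate drifts across a
  band edge (e.g. exercise onset doubling the rate) need a wider
  `band_width` or segment-wise processing.
* The admissibility thresholds (1% energy floor, median-in-band) are
  heuristics validated on synthetic signals only.
* WFDB support covers header + signal formats 212/16/80 and beat
  annotations — the subset needed for standard arrhythmia-database
  records; EDF+ annotations and vendor formats are out of scope.
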