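# wavehr

Continuous heart-rate estimation from ECG and PPG signals by oscillatory
wavelet-pattern tracking, with a classical R-peak baseline, Bland–Altman
agreement statistics, LF/HF spectral indices and a synthetic signal
generator with exact rate ground truth.

## The problem

The conventional way to measure heart rate (HR) locates the R-peak of each
QRS complex and reports one rate value per beat, ν = 1/T, where T is the
inter-beat (RR) interval.  The resulting series is non-equidistant, sampled
at roughly 1 Hz, and must be interpolated before any spectral analysis of
heart-rate variability (HRV) — leaving only a handful of points per cycle
of the HF band (0.15–0.4 Hz).  Contour analysis also breaks down on noisy
or deformed waveforms: PPG during walking, differentiated PPG channels,
arrhythmic QRS morphology.

`wavehr` instead treats the cardiac rhythm as an oscillatory component of
the signal and tracks it on the time–frequency plane:

1. **CWT energy surface.**  The Morlet continuous wavelet transform

   W(f, t₀) = f · Σₜ x(t) ψ*(f·(t − t₀)) Δt,   ψ(η) = π^(−1/4) e^(2πjη) e^(−η²/2),

   is evaluated on a linear frequency grid, and E(f, t₀) = |W(f, t₀)|² is
   the energy surface.  The parameter f acts directly as pseudo-frequency
   in Hz.
2. **Skeleton.**  At each analysis time the local maxima of E(·, t) along
   frequency (zero first, negative second derivative) form the skeleton,
   capped at the 25 largest maxima.
3. **ε-linking.**  Skeleton points at consecutive times whose frequencies
   differ by at most ε = 0.04 Hz are chained into *oscillatory patterns* —
   each pattern tracks one oscillatory component through time.
4. **Band tracking.**  The fundamental cardiac frequency Fmain (≈ 1 Hz at
   rest) is taken from the full-length FFT spectrum; the dominant pattern
   inside [0.8·Fmain, 1.2·Fmain] supplies the continuous HR curve, and the
   band around the second harmonic ([1.6, 2.4] Hz at Fmain = 1), divided
   by two, provides an independent estimate used as a consistency check
   and gap filler.

The output is an equidistant HR series at one tenth of the input sampling
rate (25 Hz for 250 Hz input) — far denser than the beat-wise series — and
the same algorithm runs unchanged on ECG, PPG and differentiated PPG.

## Worked example

```python
import wavehr as wh

cfg = wh.SyntheticConfig(duration=300.0, seed=42)   # resting subject, 60 bpm,
record, truth = wh.make_record(cfg)                 # LF+HF rate modulation

fund, harm, diag = wh.detect_hr(record)
hr = wh.reconcile(fund, harm)
print(f"Fmain {diag['fmain']:.3f} Hz; {len(hr)} samples at {hr.fs_out:g} Hz")

ann = wh.detect_rpeaks(record)                      # classical baseline
base = wh.to_equidistant(wh.annotations_to_hr(ann, record.fs), 25.0, 15.0, 285.0)
rep = wh.bland_altman(hr.crop(15.0, 285.0), base)
print(f"mean diff {rep.ba_mean_diff:+.4f} Hz, "
      f"LoA [{rep.ba_loa_lo:+.4f}, {rep.ba_loa_hi:+.4f}] Hz, "
      f"max discrepancy {rep.max_rel_discrepancy:.2f} %")

idx = wh.spectral_indices(hr)
print(f"LF_n {idx.lf_n:.3f}, HF_n {idx.hf_n:.3f}, LF/HF {idx.lf_hf:.2f}")
```

prints

```
Fmain 1.000 Hz; 7500 samples at 25 Hz
mean diff +0.0001 Hz, LoA [-0.0247, +0.0250] Hz, max discrepancy 2.80 %
LF_n 0.800, HF_n 0.199, LF/HF 4.02
```

The wavelet estimate and the R-peak baseline agree to a mean difference of
10⁻⁴ Hz with limits of agreement of ±0.025 Hz and a worst-case discrepancy
below 3%.  The LF/HF ratio of the *estimated* series (4.02) is larger than
that of the generator's ground-truth rate (1.00) because ridge tracking
smooths rate modulation over the wavelet envelope, which damps the HF band
more than the LF band — see `docs/methods.md` for the quantitative bound.

A command-line interface covers the same workflow:

```sh
wavehr simulate --preset rest --duration 300 --seed 42 --out rec.csv
wavehr detect --input rec.csv --format csv --fs 250 --out hr.csv --harmonic-check
wavehr rpeaks --input rec.csv --format csv --fs 250 --out ann.csv
wavehr rr2hr --ann ann.csv --fs 250 --fs-out 25 --out hr_rpeak.csv
wavehr compare --a hr.csv --b hr_rpeak.csv --report agreement.json
wavehr hrv --input hr.csv --out indices.json
```

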