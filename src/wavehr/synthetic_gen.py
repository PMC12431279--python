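"""Synthetic ECG/PPG generation with exact instantaneous-rate ground truth.

The instantaneous heart rate is a prescribed function

    HR(t) = mean_rate + lf_amp*sin(2*pi*lf_freq*t)
                      + hf_amp*sin(2*pi*hf_freq*t) + jitter(t),

with slow (LF, around 0.1 Hz) and fast (HF, around 0.3 Hz) autonomic-like
modulation and optional smooth random jitter (white noise low-passed at
0.4 Hz so the truth stays inside the HF band).  Beats are placed by
integrate-and-fire: beat times are the crossings of the rate integral
through successive integers, so the integral of HR between consecutive
beats is exactly one — the ground truth is exact by construction, not a
post-hoc fit.

Morphology templates are deliberately minimal: a narrow biphasic
Gaussian-derivative R-wave with small P/T bumps for ECG, and a smooth
asymmetric pulse (fast rise, slow decay, dicrotic bump) for PPG, with a
first-difference variant standing in for differential PPG hardware.  The
wavelet method under test relies on the ~1 Hz periodicity and its
harmonics, not on waveform fidelity.

Corruption adds seeded white noise at a prescribed SNR, low-frequency
baseline wander, and band-limited motion-artifact bursts inside given
time windows.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .series import HRSeries
from .signal_io import SignalRecord


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic recordings.

    Defaults mirror a resting adult recorded at 250 Hz: mean rate 1 Hz
    (60 bpm) with 0.03 Hz-amplitude LF and HF modulation at 0.1 and
    0.3 Hz.  ``artifact_windows`` is a list of ``(t_start, t_end, scale)``
    triples; each window receives a band-limited burst of ``scale`` times
    the clean-signal SD.
    """

    duration: float = 600.0
    fs: float = 250.0
    mean_rate: float = 1.0
    lf_amp: float = 0.03
    lf_freq: float = 0.1
    hf_amp: float = 0.03
    hf_freq: float = 0.3
    rate_jitter_sd: float = 0.0
    morphology: str = "ecg"
    noise_snr_db: float | None = None
    baseline_wander_amp: float = 0.0
    artifact_windows: tuple = ()
    seed: int = 0
    decimation: int = 10

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.mean_rate - self.lf_amp - self.hf_amp <= 0.3:
            raise ValueError("rate modulation leaves the physiologic range")
        if self.morphology not in ("ecg", "ppg"):
            raise ValueError("morphology must be 'ecg' or 'ppg'")
        if self.rate_jitter_sd < 0:
            raise ValueError("rate_jitter_sd must be non-negative")


def _rate_on_grid(config: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    hr = (
        config.mean_rate
        + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t)
        + config.hf_amp * np.sin(2 * np.pi * config.hf_freq * t)
    )
    if config.rate_jitter_sd > 0:
        rng = np.random.default_rng(config.seed)
        raw = rng.standard_normal(t.size)
        sos = butter(2, 0.4, btype="low", fs=config.fs, output="sos")
        smooth = sosfiltfilt(sos, raw)
        sd = smooth.std()
        if sd > 0:
            hr = hr + smooth * (config.rate_jitter_sd / sd)
    return hr


def generate_hr_truth(config: SyntheticConfig) -> HRSeries:
    """Ground-truth instantaneous rate on the ``fs/decimation`` grid."""
    n = int(round(config.duration * config.fs))
    t_full = np.arange(n) / config.fs
    hr_full = _rate_on_grid(config, t_full)
    keep = np.arange(0, n, config.decimation)
    return HRSeries(
        t_full[keep], hr_full[keep], "truth", config.fs / config.decimation
    )


def synthesize_beats(truth: HRSeries) -> np.ndarray:
    """Beat times by integrate-and-fire on the rate trace.

    Beats are the crossings of ``phase(t) = integral of HR`` through
    1, 2, 3, ...; between consecutive beats the rate integrates to
    exactly one cycle.
    """
    if np.any(truth.values <= 0):
        raise ValueError("rate must be positive")
    t = truth.times
    dt = t[1] - t[0] if t.size > 1 else 1.0
    phase = np.concatenate(([0.0], np.cumsum((truth.values[:-1] + truth.values[1:]) / 2 * dt)))
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    return np.interp(targets, phase, t)


def _add_bumps(sig: np.ndarray, t: np.ndarray, centers: np.ndarray,
               amp: float, offset: float, sigma: float, fs: float,
               derivative: bool = False) -> None:
    """Accumulate Gaussian (or Gaussian-derivative) bumps in place."""
    half = int(round(5 * sigma * fs)) + 1
    n = sig.size
    for c in centers:
        mu = c + offset
        k0 = int(round(mu * fs))
        lo, hi = max(0, k0 - half), min(n, k0 + half + 1)
        if lo >= hi:
            continue
        u = (t[lo:hi] - mu) / sigma
        if derivative:
            # normalized so the extremum magnitude equals `amp`
            sig[lo:hi] += -amp * u * np.exp(0.5 - u**2 / 2.0)
        else:
            sig[lo:hi] += amp * np.exp(-(u**2) / 2.0)


def synthesize_ecg(beat_times: np.ndarray, config: SyntheticConfig) -> SignalRecord:
    """ECG-like signal: biphasic R spikes plus low P/T bumps."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() > config.duration):
        raise ValueError("beat times outside the record duration")
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)
    # R wave: narrow biphasic Gaussian derivative, ~30 ms, amplitude 1.
    _add_bumps(sig, t, beat_times, 1.0, 0.0, 0.010, config.fs, derivative=True)
    _add_bumps(sig, t, beat_times, 0.15, -0.18, 0.035, config.fs)  # P
    _add_bumps(sig, t, beat_times, 0.30, 0.25, 0.060, config.fs)  # T
    return SignalRecord(sig, config.fs, kind="ECG", label="synthetic ECG")


def synthesize_ppg(
    beat_times: np.ndarray, config: SyntheticConfig, differentiate: bool = False
) -> SignalRecord:
    """Smooth asymmetric pulse waves; optionally the PPGd first difference."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() > config.duration):
        raise ValueError("beat times outside the record duration")
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    sig = np.zeros(n)
    # Asymmetric systolic wave: fast rise (~0.15 s), slow decay (~0.45 s),
    # built from a narrow leading and a wide trailing Gaussian.
    _add_bumps(sig, t, beat_times, 1.0, 0.15, 0.065, config.fs)
    _add_bumps(sig, t, beat_times, 0.55, 0.32, 0.160, config.fs)
    _add_bumps(sig, t, beat_times, 0.18, 0.42, 0.060, config.fs)  # dicrotic bump
    if differentiate:
        sig = np.diff(sig, prepend=sig[0]) * config.fs
        return SignalRecord(sig, config.fs, kind="PPGd", label="synthetic PPGd")
    return SignalRecord(sig, config.fs, kind="PPG", label="synthetic PPG")


def corrupt(record: SignalRecord, config: SyntheticConfig) -> SignalRecord:
    """Add seeded white noise, baseline wander and motion-artifact bursts.

    The white-noise level is scaled so the empirical variance ratio hits
    ``noise_snr_db`` exactly.  Artifact bursts are 0.5-10 Hz band-limited
    noise with cosine-tapered edges, ``scale`` times the clean-signal SD.
    With ``noise_snr_db=None``, no wander and no windows, the record is
    returned unchanged.
    """
    cfg = config
    has_noise = cfg.noise_snr_db is not None and np.isfinite(cfg.noise_snr_db)
    if not has_noise and cfg.baseline_wander_amp == 0 and not cfg.artifact_windows:
        return record
    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    x = record.samples.copy()
    n = x.size
    sd = x.std()
    t = record.times
    if has_noise:
        noise = rng.standard_normal(n)
        target_var = x.var() / 10.0 ** (cfg.noise_snr_db / 10.0)
        noise *= np.sqrt(target_var / noise.var())
        x = x + noise
    if cfg.baseline_wander_amp > 0:
        sos = butter(2, 0.5, btype="low", fs=record.fs, output="sos")
        wander = sosfiltfilt(sos, rng.standard_normal(n))
        wsd = wander.std()
        if wsd > 0:
            x = x + wander * (cfg.baseline_wander_amp * sd / wsd)
    for (t_start, t_end, scale) in cfg.artifact_windows:
        sel = (t >= t_start) & (t < t_end)
        m = int(sel.sum())
        if m < 8:
            continue
        sos = butter(2, [0.5, min(10.0, 0.45 * record.fs)], btype="band",
                     fs=record.fs, output="sos")
        burst = sosfiltfilt(sos, rng.standard_normal(m))
        bsd = burst.std()
        if bsd > 0:
            taper = np.hanning(min(m, int(record.fs)))  # ~0.5 s ramps
            ramp = taper[: taper.size // 2]
            window = np.ones(m)
            window[: ramp.size] = ramp
            window[-ramp.size:] = ramp[::-1]
            x[sel] = x[sel] + burst * (scale * sd / bsd) * window
    return SignalRecord(x, record.fs, kind=record.kind,
                        label=record.label + " + noise", t0=record.t0)


def make_record(config: SyntheticConfig) -> tuple[SignalRecord, HRSeries]:
    """Convenience: truth -> beats -> morphology -> corruption."""
    truth = generate_hr_truth(config)
    beats = synthesize_beats(truth)
    if config.morphology == "ecg":
        rec = synthesize_ecg(beats, config)
    else:
        rec = synthesize_ppg(beats, config)
    return corrupt(rec, config), truth
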