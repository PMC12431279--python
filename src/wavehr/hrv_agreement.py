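"""Agreement statistics and spectral indices for HR series.

Two HR series with different native rates (e.g. the 25 Hz wavelet
estimate and the ~1 Hz interpolated beat-wise rate) are compared after
linear resampling onto the finer of the two grids restricted to their
overlap.  Agreement is summarized by the mean absolute difference, the
Bland-Altman mean difference with 1.96-SD limits of agreement (plus
standard confidence intervals), and the maximum relative discrepancy.

Spectral indices follow the standard HRV band convention — VLF
[0.0033, 0.04), LF [0.04, 0.15), HF [0.15, 0.4] Hz — computed on the
amplitude spectrum of the mean-removed, Hann-tapered series and
normalized by the VLF+LF+HF total, so the three indices sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

from .series import HRSeries

logger = logging.getLogger(__name__)

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class SpectralIndices:
    """Normalized VLF/LF/HF amplitudes (sum to one) and the LF/HF ratio."""

    vlf_n: float
    lf_n: float
    hf_n: float
    lf_hf: float


@dataclass
class AgreementReport:
    """Pairwise agreement between two HR series (all rates in Hz)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_abs_diff: float
    ba_mean_diff: float
    ba_loa_lo: float
    ba_loa_hi: float
    ba_ci_mean: tuple[float, float]
    ba_ci_loa_lo: tuple[float, float]
    ba_ci_loa_hi: tuple[float, float]
    pct_outside_loa: float
    max_rel_discrepancy: float
    n: int

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


def align(a: HRSeries, b: HRSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample both series to the finer grid over their time overlap."""
    t0 = max(a.times[0], b.times[0])
    t1 = min(a.times[-1], b.times[-1])
    if t1 <= t0:
        raise ValueError("series do not overlap in time")
    finer = a if a.fs_out >= b.fs_out else b
    sel = (finer.times >= t0) & (finer.times <= t1)
    grid = finer.times[sel]
    if grid.size == 0:
        raise ValueError("overlap contains no samples")
    av = np.interp(grid, a.times, a.values)
    bv = np.interp(grid, b.times, b.values)
    return grid, av, bv


def summary_stats(hr: HRSeries) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1) of the rate."""
    if len(hr) == 0:
        raise ValueError("empty series")
    mean = float(np.mean(hr.values))
    sd = float(np.std(hr.values, ddof=1)) if len(hr) > 1 else 0.0
    return mean, sd


def mean_abs_diff(a: HRSeries, b: HRSeries) -> float:
    """Mean absolute pointwise difference on the common grid."""
    _, av, bv = align(a, b)
    return float(np.mean(np.abs(av - bv)))


def bland_altman(a: HRSeries, b: HRSeries) -> AgreementReport:
    """Bland-Altman agreement of two HR series.

    Differences ``d = a - b`` on the common grid; limits of agreement are
    ``mean(d) +/- 1.96*SD(d)`` with the usual standard errors
    (``SD/sqrt(n)`` for the mean, ``SD*sqrt(1/n + 1.96**2/(2(n-1)))`` for
    each limit).
    """
    _, av, bv = align(a, b)
    d = av - bv
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 aligned points")
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo, loa_hi = md - 1.96 * sd, md + 1.96 * sd
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    outside = np.sum((d < loa_lo) | (d > loa_hi))
    mean_a, sd_a = float(np.mean(av)), float(np.std(av, ddof=1))
    mean_b, sd_b = float(np.mean(bv)), float(np.std(bv, ddof=1))
    with np.errstate(divide="ignore"):
        max_rel = (
            float(100.0 * np.max(np.abs(d) / bv)) if np.all(bv > 0) else float("nan")
        )
    return AgreementReport(
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        mean_abs_diff=float(np.mean(np.abs(d))),
        ba_mean_diff=md,
        ba_loa_lo=loa_lo,
        ba_loa_hi=loa_hi,
        ba_ci_mean=(md - 1.96 * se_mean, md + 1.96 * se_mean),
        ba_ci_loa_lo=(loa_lo - 1.96 * se_loa, loa_lo + 1.96 * se_loa),
        ba_ci_loa_hi=(loa_hi - 1.96 * se_loa, loa_hi + 1.96 * se_loa),
        pct_outside_loa=float(100.0 * outside / n),
        max_rel_discrepancy=max_rel,
        n=n,
    )


def max_rel_discrepancy(
    a: HRSeries, b: HRSeries, exclude: np.ndarray | None = None
) -> float:
    """``100 * max |a - b| / b`` on the common grid (``b`` is reference).

    ``exclude`` is an optional boolean mask on the common grid (e.g.
    edge-affected samples) removed before taking the maximum.
    """
    grid, av, bv = align(a, b)
    if np.any(bv <= 0):
        raise ValueError("reference series must be positive")
    rel = 100.0 * np.abs(av - bv) / bv
    if exclude is not None:
        rel = rel[~exclude]
        if rel.size == 0:
            raise ValueError("all samples excluded")
    return float(np.max(rel))


def _band_amplitude(freqs: np.ndarray, amp: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float(amp[sel].sum())


def spectral_indices(hr: HRSeries) -> SpectralIndices:
    """Normalized VLF/LF/HF amplitudes and LF/HF ratio of an HR series.

    Durations below 125 s (five LF periods at the 0.04 Hz band edge)
    trigger a warning: the LF estimate is then poorly resolved.
    """
    if len(hr) < 8:
        raise ValueError("series too short for spectral analysis")
    if hr.duration < 125.0:
        logger.warning(
            "series of %.0f s is short for LF resolution (>= 125 s advised)",
            hr.duration,
        )
    x = hr.values - hr.values.mean()
    if np.allclose(x, 0):
        raise ValueError("constant series has no spectral content")
    amp = np.abs(rfft(x * get_window("hann", x.size)))
    freqs = rfftfreq(x.size, 1.0 / hr.fs_out)
    vlf = _band_amplitude(freqs, amp, VLF_BAND)
    lf = _band_amplitude(freqs, amp, LF_BAND)
    # HF band is closed at 0.4 Hz.
    sel_hf = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    hf = float(amp[sel_hf].sum())
    total = vlf + lf + hf
    if total == 0 or hf == 0:
        raise ValueError("no spectral amplitude in the HRV bands (or HF empty)")
    return SpectralIndices(
        vlf_n=vlf / total, lf_n=lf / total, hf_n=hf / total, lf_hf=lf / hf
    )
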