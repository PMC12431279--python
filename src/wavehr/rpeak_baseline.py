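"""Classical contour-analysis heart-rate baseline.

R-peaks are detected with the classical derivative/energy recipe
(band-pass, differentiate, square, 150 ms moving-window integration,
adaptive dual thresholds with search-back, 0.25 s refractory period), the
non-equidistant beat-to-beat rate ``nu_i = 1/T_i`` is formed at interval
midpoints, and linear interpolation transfers it to an equidistant grid
for comparison with the continuous wavelet estimate.  For PPG the same
thresholding logic runs on a smoothed version of the pulse wave and
reports systolic peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .series import HRSeries
from .signal_io import BeatAnnotations, SignalRecord

REFRACTORY_S = 0.25  # physiologic lower bound on the RR interval


@dataclass
class NonEquidistantHR:
    """Beat-to-beat heart rate at interval midpoints (non-equidistant)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("HR values must be positive")

    def __len__(self) -> int:
        return self.times.size


def _detection_function(record: SignalRecord) -> np.ndarray:
    """Pan-Tompkins-style detection function (moving-window integral)."""
    fs = record.fs
    x = record.samples - record.samples.mean()
    if record.kind in ("PPG", "PPGd"):
        sos = butter(2, [0.5, min(8.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
        return sosfiltfilt(sos, x)
    sos = butter(2, [5.0, min(15.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    der = np.gradient(bp) * fs
    sq = der**2
    win = max(1, int(round(0.150 * fs)))
    return np.convolve(sq, np.ones(win) / win, mode="same")


def _candidate_peaks(det: np.ndarray, fs: float) -> np.ndarray:
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(det, distance=max(1, int(round(REFRACTORY_S * fs))))
    return peaks


def _adaptive_select(det: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive dual-threshold selection with missed-beat search-back."""
    if peaks.size == 0:
        return peaks
    # Initialize from the first two seconds of candidates.
    init = peaks[peaks < 2 * fs]
    spk = det[init].max() if init.size else det[peaks].max()
    npk = det[init].mean() * 0.5 if init.size else 0.0
    thr = npk + 0.25 * (spk - npk)
    accepted: list[int] = []
    rr_hist: list[float] = []
    last = -np.inf
    for p in peaks:
        if det[p] >= thr:
            if accepted and (p - accepted[-1]) / fs < REFRACTORY_S:
                if det[p] > det[accepted[-1]]:
                    accepted[-1] = int(p)
                continue
            if accepted:
                rr_hist.append((p - accepted[-1]) / fs)
                rr_hist = rr_hist[-8:]
            accepted.append(int(p))
            last = p
            spk = 0.125 * det[p] + 0.875 * spk
        else:
            npk = 0.125 * det[p] + 0.875 * npk
        thr = npk + 0.25 * (spk - npk)
        # Search-back: if 1.66x the running mean RR elapsed with no beat,
        # accept the best sub-threshold candidate in the lapse.
        if rr_hist and accepted:
            mean_rr = float(np.mean(rr_hist))
            if (p - last) / fs > 1.66 * mean_rr:
                lapse = peaks[(peaks > last) & (peaks < p)]
                lapse = lapse[det[lapse] >= 0.5 * thr]
                if lapse.size:
                    best = int(lapse[np.argmax(det[lapse])])
                    if (best - accepted[-1]) / fs >= REFRACTORY_S:
                        accepted.append(best)
                        accepted.sort()
                        spk = 0.25 * det[best] + 0.75 * spk
                        last = best
    return np.asarray(accepted, dtype=np.int64)


def detect_rpeaks(record: SignalRecord) -> BeatAnnotations:
    """Detect R-peaks (ECG) or systolic peaks (PPG).

    Peak positions are refined to the local signal maximum within
    +/-100 ms of the detection-function flag.  No two peaks are closer
    than the 0.25 s refractory period.

    Raises
    ------
    ValueError
        For records shorter than 5 s or with zero variance.
    """
    if record.duration < 5.0:
        raise ValueError("record shorter than 5 s")
    if np.std(record.samples) == 0:
        raise ValueError("zero-variance signal")
    fs = record.fs
    det = _detection_function(record)
    peaks = _adaptive_select(det, _candidate_peaks(det, fs), fs)
    # Refine to the local maximum of the raw signal.
    half = int(round(0.100 * fs))
    x = record.samples
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.asarray(sorted(set(refined)), dtype=np.int64)
    if refined.size > 1:  # refinement can merge neighbors; re-enforce refractory
        keep = [0]
        for i in range(1, refined.size):
            if (refined[i] - refined[keep[-1]]) / fs >= REFRACTORY_S:
                keep.append(i)
            elif x[refined[i]] > x[refined[keep[-1]]]:
                keep[-1] = i
        refined = refined[keep]
    return BeatAnnotations(refined, source="detector")


def annotations_to_hr(ann: BeatAnnotations, fs: float) -> NonEquidistantHR:
    """Beat-to-beat rate ``nu_i = 1/T_i`` at interval midpoints."""
    if len(ann) < 2:
        raise ValueError("need at least two beats")
    idx = ann.peak_indices
    intervals = np.diff(idx) / fs
    if np.any(intervals <= 0):
        raise ValueError("duplicate or non-increasing beat indices")
    times = (idx[:-1] + idx[1:]) / (2.0 * fs)
    return NonEquidistantHR(times, 1.0 / intervals)


def to_equidistant(
    hr: NonEquidistantHR, fs_out: float, t_start: float, t_end: float,
    provenance: str = "rpeak",
) -> HRSeries:
    """Linear interpolation of a beat-wise rate onto an equidistant grid."""
    if len(hr) < 2:
        raise ValueError("need at least two rate points")
    if t_start < hr.times[0] or t_end > hr.times[-1]:
        raise ValueError(
            f"grid [{t_start}, {t_end}] extends beyond the data span "
            f"[{hr.times[0]:.3f}, {hr.times[-1]:.3f}]; extrapolation refused"
        )
    n = int(np.floor((t_end - t_start) * fs_out)) + 1
    times = t_start + np.arange(n) / fs_out
    values = np.interp(times, hr.times, hr.values)
    return HRSeries(times, values, provenance, fs_out)
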