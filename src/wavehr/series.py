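"""Equidistant instantaneous heart-rate series.

The package expresses heart rate in Hz (beats per second, ``nu = 1/T``)
rather than beats per minute, because every downstream spectral quantity
(LF/HF bands, ridge frequencies) lives on the Hz axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed provenance tags for an HR series.
PROVENANCES = ("pattern-fundamental", "pattern-harmonic", "rpeak", "expert", "truth")


@dataclass
class HRSeries:
    """An equidistant instantaneous heart-rate trace.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, equidistant and increasing.
    values : ndarray
        Instantaneous heart rate in Hz; positive and finite.
    provenance : str
        Which method produced the series; one of :data:`PROVENANCES`.
    fs_out : float
        Output sampling rate in Hz (``1 / (times[1] - times[0])``).
    gaps : ndarray of bool, optional
        Marks samples whose value was filled rather than measured
        (ridge dropouts, edge regions).  ``None`` means no gaps.
    sample_provenance : ndarray of object, optional
        Per-sample provenance after reconciliation of several sources.
    """

    times: np.ndarray
    values: np.ndarray
    provenance: str
    fs_out: float
    gaps: np.ndarray | None = None
    sample_provenance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size == 0:
            raise ValueError("HRSeries must contain at least one sample")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("HRSeries times must be equidistant")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("HR values must be positive and finite")
        if self.fs_out <= 0:
            raise ValueError("fs_out must be positive")
        if self.gaps is not None:
            self.gaps = np.asarray(self.gaps, dtype=bool)
            if self.gaps.shape != self.values.shape:
                raise ValueError("gaps mask must match values")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span of the series in seconds."""
        return float(self.times[-1] - self.times[0])

    def crop(self, t_start: float, t_end: float) -> "HRSeries":
        """Return the sub-series with ``t_start <= t <= t_end``."""
        sel = (self.times >= t_start) & (self.times <= t_end)
        if not np.any(sel):
            raise ValueError("crop window contains no samples")
        return HRSeries(
            self.times[sel],
            self.values[sel],
            self.provenance,
            self.fs_out,
            gaps=None if self.gaps is None else self.gaps[sel],
            sample_provenance=(
                None if self.sample_provenance is None else self.sample_provenance[sel]
            ),
        )
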