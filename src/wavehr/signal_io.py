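"""Reading and writing physiological-signal and annotation formats.

Supported inputs are WFDB records (``.hea`` header + ``.dat`` signal,
``.atr``/``.qrs`` beat annotations; signal formats 212, 16 and 80, which
cover the MIT-BIH Arrhythmia Database), EDF (through :mod:`mne`, imported
lazily) and plain CSV with an explicitly supplied sampling rate.  Loaded
signals are never resampled or filtered: the sample sequence on disk is the
sample sequence returned.

The WFDB reader is intentionally minimal and self-contained; it parses the
published header/signal/annotation byte layouts directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import HRSeries

SIGNAL_KINDS = ("ECG", "PPG", "PPGd", "synthetic")

# MIT annotation codes that denote beats (normal and ectopic alike);
# rhythm-change / noise / comment codes are dropped on load.
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38})


@dataclass
class SignalRecord:
    """A single-channel physiological signal.

    Attributes
    ----------
    samples : ndarray
        Signal amplitudes in arbitrary units (e.g. mV).
    fs : float
        Sampling rate in Hz; the sampling period is ``1/fs``.
    kind : str
        One of ``ECG``, ``PPG``, ``PPGd``, ``synthetic``.
    label : str
        Free-text channel name.
    t0 : float
        Start-time offset in seconds.
    """

    samples: np.ndarray
    fs: float
    kind: str = "synthetic"
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class BeatAnnotations:
    """Beat locations as sample indices into a companion record."""

    peak_indices: np.ndarray
    source: str = "detector"

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.peak_indices.ndim != 1:
            raise ValueError("peak_indices must be 1-D")
        if self.peak_indices.size > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.source not in ("detector", "expert"):
            raise ValueError(f"unknown annotation source {self.source!r}")

    def __len__(self) -> int:
        return self.peak_indices.size

    def times(self, fs: float) -> np.ndarray:
        """Beat times in seconds at sampling rate ``fs``."""
        return self.peak_indices / fs


# ---------------------------------------------------------------------------
# WFDB
# ---------------------------------------------------------------------------

def _parse_wfdb_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header {hea_path}")
    rec = lines[0].split()
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    channels = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = float(b.rstrip(")"))
            if g:
                gain = float(g)
        adc_zero = float(tok[4]) if len(tok) > 4 else 0.0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(channels)}"
        channels.append(
            {
                "file": tok[0],
                "fmt": fmt,
                "gain": gain if gain != 0 else 200.0,
                "baseline": baseline,
                "units": units,
                "desc": desc,
            }
        )
    return {"fs": fs, "n_samples": n_samples, "n_sig": n_sig, "channels": channels}


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = b.size // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s0 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    s1 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(n_pairs * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096
    return out[:n_values]


def _read_wfdb_signal(dat_path: Path, hdr: dict, channel_idx: int) -> np.ndarray:
    fmt = hdr["channels"][channel_idx]["fmt"]
    n_sig_in_file = sum(1 for c in hdr["channels"] if c["file"] == hdr["channels"][channel_idx]["file"])
    raw = dat_path.read_bytes()
    if fmt == 212:
        total = _decode_212(raw, (len(raw) // 3) * 2)
    elif fmt == 16:
        total = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif fmt == 80:
        total = np.frombuffer(raw, dtype=np.uint8).astype(np.int32) - 128
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    # Samples of multi-signal files are interleaved frame by frame.
    pos = sum(
        1
        for c in hdr["channels"][:channel_idx]
        if c["file"] == hdr["channels"][channel_idx]["file"]
    )
    n_frames = total.size // n_sig_in_file
    sig = total[: n_frames * n_sig_in_file].reshape(-1, n_sig_in_file)[:, pos]
    if hdr["n_samples"]:
        sig = sig[: hdr["n_samples"]]
    ch = hdr["channels"][channel_idx]
    return (sig - ch["baseline"]) / ch["gain"]


def _read_wfdb_annotations(path: Path) -> np.ndarray:
    """Decode a MIT-format annotation file into beat sample indices."""
    raw = path.read_bytes()
    indices: list[int] = []
    t = 0
    i = 0
    n = len(raw)
    while i + 1 < n:
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        inc = word & 0x3FF
        if code == 0 and inc == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte interval follows (PDP-11 word order)
            if i + 3 >= n:
                break
            t += (
                ((raw[i] | (raw[i + 1] << 8)) << 16)
                | (raw[i + 2] | (raw[i + 3] << 8))
            )
            i += 4
        elif code == 63:  # AUX: skip payload (padded to even length)
            i += inc + (inc % 2)
        elif code in (60, 61, 62):  # NUM / SUB / CHN: no time advance
            continue
        else:
            t += inc
            if code in _BEAT_CODES:
                indices.append(t)
    return np.asarray(indices, dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_record(
    path: str | os.PathLike,
    format: str | None = None,
    channel: int | str = 0,
    fs: float | None = None,
    kind: str | None = None,
) -> SignalRecord:
    """Load one channel of a signal file into a :class:`SignalRecord`.

    Parameters
    ----------
    path : path-like
        For WFDB, either the ``.hea`` file or the record base name.
    format : {'wfdb', 'edf', 'csv'}, optional
        Inferred from the file suffix when omitted.
    channel : int or str
        Channel index or name.
    fs : float, optional
        Sampling rate in Hz — required for CSV (a bare CSV has no header
        metadata); ignored for WFDB/EDF, whose headers carry it.
    kind : str, optional
        Override the signal-kind tag; guessed from the channel label
        otherwise.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".hea": "wfdb", ".dat": "wfdb", ".edf": "edf", ".csv": "csv"}.get(
            suffix, "wfdb" if not suffix else None
        )
        if format is None:
            raise ValueError(f"cannot infer format of {path}")

    if format == "csv":
        if fs is None:
            raise ValueError("CSV input requires an explicit sampling rate fs")
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
        if isinstance(channel, int):
            if channel >= df.shape[1]:
                raise KeyError(f"channel index {channel} out of range")
            col = df.columns[channel]
        else:
            if channel not in df.columns:
                raise KeyError(f"channel {channel!r} not in {list(df.columns)}")
            col = channel
        samples = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        return SignalRecord(samples, fs, kind=kind or "synthetic", label=str(col))

    if format == "wfdb":
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        if not hea.exists():
            raise FileNotFoundError(hea)
        hdr = _parse_wfdb_header(hea)
        if isinstance(channel, str):
            descs = [c["desc"] for c in hdr["channels"]]
            if channel not in descs:
                raise KeyError(f"channel {channel!r} not in {descs}")
            channel = descs.index(channel)
        if channel >= hdr["n_sig"]:
            raise KeyError(f"channel index {channel} out of range")
        dat = hea.parent / hdr["channels"][channel]["file"]
        if not dat.exists():
            raise FileNotFoundError(dat)
        samples = _read_wfdb_signal(dat, hdr, channel)
        label = hdr["channels"][channel]["desc"]
        return SignalRecord(
            samples, hdr["fs"], kind=kind or _guess_kind(label), label=label
        )

    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF support requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        if isinstance(channel, int):
            if channel >= len(names):
                raise KeyError(f"channel index {channel} out of range")
            name = names[channel]
        else:
            if channel not in names:
                raise KeyError(f"channel {channel!r} not in {names}")
            name = channel
        data = raw.get_data(picks=[name])[0]
        return SignalRecord(
            data, float(raw.info["sfreq"]), kind=kind or _guess_kind(name), label=name
        )

    raise ValueError(f"unknown format {format!r}")


def _guess_kind(label: str) -> str:
    low = label.lower()
    if "ppgd" in low or "dppg" in low:
        return "PPGd"
    if "ppg" in low or "pleth" in low or "pulse" in low:
        return "PPG"
    if "ecg" in low or "ekg" in low or low.startswith(("ml", "v", "ii", "i ")):
        return "ECG"
    return "synthetic"


def read_annotations(
    path: str | os.PathLike, format: str | None = None, source: str = "expert"
) -> BeatAnnotations:
    """Read beat annotations (WFDB ``.atr`` or a CSV of sample indices)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "wfdb"
    if format == "csv":
        text = path.read_text().strip()
        tokens = text.replace("\n", ",").split(",")
        tokens = [t.strip() for t in tokens if t.strip()]
        if tokens and not tokens[0].lstrip("-").isdigit():
            tokens = tokens[1:]  # header row
        idx = np.asarray([int(t) for t in tokens], dtype=np.int64)
    elif format == "wfdb":
        idx = _read_wfdb_annotations(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if idx.size == 0:
        raise ValueError(f"no beat annotations found in {path}")
    return BeatAnnotations(idx, source=source)


def write_hr(hr: HRSeries, path: str | os.PathLike) -> None:
    """Write an HR series as CSV (``time_s,hr_hz,provenance``)."""
    if len(hr) == 0:
        raise ValueError("refusing to write an empty HR series")
    prov = (
        hr.sample_provenance
        if hr.sample_provenance is not None
        else np.full(len(hr), hr.provenance, dtype=object)
    )
    df = pd.DataFrame({"time_s": hr.times, "hr_hz": hr.values, "provenance": prov})
    df.to_csv(path, index=False, float_format="%.12g")


def read_hr(path: str | os.PathLike) -> HRSeries:
    """Read an HR series written by :func:`write_hr`."""
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    values = df["hr_hz"].to_numpy(dtype=float)
    prov = df["provenance"].astype(str).to_numpy()
    fs_out = 1.0 / (times[1] - times[0]) if times.size > 1 else 1.0
    main = str(prov[0]) if len(set(prov)) == 1 else "pattern-fundamental"
    return HRSeries(times, values, main, fs_out, sample_provenance=prov)
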