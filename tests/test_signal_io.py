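"""Signal/annotation I/O: CSV round trips and the WFDB byte formats.

The WFDB fixtures are synthetic records whose bytes are assembled here
from the published format layout (212-packing, little-endian 16-bit,
MIT annotation words), so the format definition itself is the oracle.
"""

import numpy as np
import pytest

from wavehr.series import HRSeries
from wavehr.signal_io import (
    BeatAnnotations,
    SignalRecord,
    read_annotations,
    read_hr,
    read_record,
    write_hr,
)


def _pack_212(values):
    """Independent byte-level encoder for WFDB format 212."""
    vals = list(values)
    if len(vals) % 2:
        vals.append(0)
    out = bytearray()
    for a, b in zip(vals[0::2], vals[1::2]):
        a &= 0xFFF
        b &= 0xFFF
        out.append(a & 0xFF)
        out.append(((a >> 8) & 0x0F) | ((b >> 8) << 4))
        out.append(b & 0xFF)
    return bytes(out)


def _write_wfdb_record(tmp_path, name, ch0, ch1, fs=250, fmt=212):
    """Two-channel synthetic WFDB record (integer ADC units, gain 200)."""
    n = len(ch0)
    hea = tmp_path / f"{name}.hea"
    hea.write_text(
        f"{name} 2 {fs} {n}\n"
        f"{name}.dat {fmt} 200 12 0 {ch0[0]} 0 0 ECG1\n"
        f"{name}.dat {fmt} 200 12 0 {ch1[0]} 0 0 PPG1\n"
    )
    interleaved = [v for pair in zip(ch0, ch1) for v in pair]
    if fmt == 212:
        payload = _pack_212(interleaved)
    else:
        payload = np.asarray(interleaved, dtype="<i2").tobytes()
    (tmp_path / f"{name}.dat").write_bytes(payload)
    return hea


def _write_atr(tmp_path, name, indices, codes=None):
    """MIT annotation file: (code << 10) | interval words, EOF word."""
    codes = codes or [1] * len(indices)
    out = bytearray()
    prev = 0
    for idx, code in zip(indices, codes):
        interval = idx - prev
        prev = idx
        word = (code << 10) | (interval & 0x3FF)
        out += word.to_bytes(2, "little")
    out += (0).to_bytes(2, "little")
    path = tmp_path / f"{name}.atr"
    path.write_bytes(bytes(out))
    return path


class TestSignalRecord:
    def test_rejects_nonfinite_and_bad_fs(self):
        with pytest.raises(ValueError):
            SignalRecord(np.array([1.0, np.nan]), 250.0)
        with pytest.raises(ValueError):
            SignalRecord(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            SignalRecord(np.array([]), 250.0)

    def test_times_and_duration(self):
        rec = SignalRecord(np.arange(5, dtype=float), 250.0, t0=1.0)
        assert rec.duration == pytest.approx(0.02)
        assert rec.times[0] == 1.0


class TestCsvRecord:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("v\n" + "\n".join(f"{x}" for x in [0.1, -0.2, 0.3, 0.0, 5.0]))
        rec = read_record(path, format="csv", fs=250.0)
        assert len(rec) == 5
        assert rec.fs == 250.0
        np.testing.assert_allclose(rec.samples, [0.1, -0.2, 0.3, 0.0, 5.0])

    def test_requires_fs(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("v\n1\n2\n")
        with pytest.raises(ValueError, match="fs"):
            read_record(path, format="csv")

    def test_unknown_channel(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("v\n1\n2\n")
        with pytest.raises(KeyError):
            read_record(path, format="csv", fs=250.0, channel="missing")

    def test_non_numeric_samples_fail(self, tmp_path):
        path = tmp_path / "sig.csv"
        path.write_text("v\n1\nhello\n")
        with pytest.raises(Exception):
            read_record(path, format="csv", fs=250.0)


class TestWfdb:
    @pytest.mark.parametrize("fmt", [212, 16])
    def test_reads_back_adc_values(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        ch0 = rng.integers(-2048, 2047, size=100).tolist()
        ch1 = rng.integers(-2048, 2047, size=100).tolist()
        hea = _write_wfdb_record(tmp_path, "rec", ch0, ch1, fmt=fmt)
        rec0 = read_record(hea, format="wfdb", channel=0)
        rec1 = read_record(hea, format="wfdb", channel="PPG1")
        assert rec0.fs == 250.0
        assert len(rec0) == 100
        # gain 200, baseline 0 -> physical = adc / 200
        np.testing.assert_allclose(rec0.samples, np.asarray(ch0) / 200.0)
        np.testing.assert_allclose(rec1.samples, np.asarray(ch1) / 200.0)

    def test_no_silent_resampling(self, tmp_path):
        ch = list(range(-50, 50))
        hea = _write_wfdb_record(tmp_path, "rec", ch, ch)
        rec = read_record(hea, format="wfdb", channel=0)
        assert len(rec) == len(ch)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_record(tmp_path / "nope.hea", format="wfdb")

    def test_annotations_beats_only(self, tmp_path):
        # codes: 1 = normal beat, 5 = PVC (kept), 28 = rhythm change (dropped)
        path = _write_atr(tmp_path, "rec", [10, 260, 510, 700], [1, 5, 28, 1])
        ann = read_annotations(path, format="wfdb")
        np.testing.assert_array_equal(ann.peak_indices, [10, 260, 700])

    def test_annotation_count_cross_check(self, tmp_path):
        """Count agrees with the independent encoder's bookkeeping."""
        idx = np.cumsum(np.full(50, 250)).tolist()
        path = _write_atr(tmp_path, "rec", idx)
        ann = read_annotations(path, format="wfdb")
        assert len(ann) == 50
        np.testing.assert_array_equal(ann.peak_indices, idx)


class TestAnnotationsCsv:
    def test_simple_list(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("10,260,510")
        ann = read_annotations(path)
        np.testing.assert_array_equal(ann.peak_indices, [10, 260, 510])

    def test_non_monotone_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("10,5")
        with pytest.raises(ValueError):
            read_annotations(path)

    def test_empty_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("index\n")
        with pytest.raises(ValueError):
            read_annotations(path)


class TestHrCsv:
    def test_round_trip_preserves_values(self, tmp_path):
        hr = HRSeries(
            np.arange(3) / 25.0,
            np.array([1.0123456789, 0.987654321, 1.1]),
            "rpeak",
            25.0,
        )
        path = tmp_path / "hr.csv"
        write_hr(hr, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time_s,hr_hz,provenance"
        assert len(lines) == 4
        back = read_hr(path)
        np.testing.assert_allclose(back.values, hr.values, rtol=1e-9)
        np.testing.assert_allclose(back.times, hr.times, rtol=1e-9)
        assert back.provenance == "rpeak"

    def test_empty_series_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            HRSeries(np.array([]), np.array([]), "rpeak", 25.0)
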