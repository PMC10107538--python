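"""Minimal EDF/EDF+ reader and writer for continuous multichannel EEG.

Only the subset of the format needed here is supported: one data-record
duration of 1 second, 16-bit little-endian samples, identical sampling rate
across channels.  Physical dimensions other than microvolts trigger a warning
and are assumed to be microvolts.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EDFFormatError", "read_edf", "write_edf", "RawEDF"]

_HEADER_LEN = 256
_SIGNAL_HEADER_LEN = 256
_DIG_MAX = 32767
_DIG_MIN = -32767


class EDFFormatError(ValueError):
    """Raised when a file cannot be parsed as EDF or lacks required signals."""


@dataclass
class RawEDF:
    """Decoded EDF content: data in physical units (µV), one row per signal."""

    labels: list[str]
    fs: float
    data: np.ndarray  # (n_signals, n_samples) float64, µV
    start_h: float  # metadata stashed by :func:`write_edf`, 0.0 if absent


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    labels: list[str],
    start_h: float = 0.0,
) -> None:
    """Write channels (rows of *data*, µV) to an EDF file.

    The signal length is padded with zeros to a whole number of 1-s records;
    the exact sample count and the age-at-start metadata are stashed in the
    recording-identification field so that :func:`read_edf` can restore them.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_sig, n_samp = data.shape
    if len(labels) != n_sig:
        raise ValueError("one label per signal required")
    fs_int = int(round(fs))
    if not math.isclose(fs, fs_int):
        raise ValueError("integer sampling rates only")
    n_records = int(math.ceil(n_samp / fs_int)) if n_samp else 0

    phys_max = float(np.max(np.abs(data))) if data.size else 1.0
    phys_max = max(phys_max, 1.0) * 1.0001  # avoid digital clipping at the rail

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field(f"Startdate X age_h={start_h:.6g} ns={n_samp}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HEADER_LEN + n_sig * _SIGNAL_HEADER_LEN), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_sig), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_field(f"EEG {lab}", 16) for lab in labels),
            b"".join(_field("AgAgCl electrode", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_field(f"{-phys_max:.6g}"[:8], 8) for _ in labels),
            b"".join(_field(f"{phys_max:.6g}"[:8], 8) for _ in labels),
            b"".join(_field(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_field("HP:0.5Hz LP:70Hz", 80) for _ in labels),
            b"".join(_field(str(fs_int), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )

    padded = np.zeros((n_sig, n_records * fs_int))
    padded[:, :n_samp] = data
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_max)
    digital = np.round((padded + phys_max) * scale + _DIG_MIN).astype("<i2")
    # records are interleaved: all samples of signal 0 for record r, then signal 1, ...
    records = digital.reshape(n_sig, n_records, fs_int).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())


def _parse_float(raw: bytes, what: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except ValueError as exc:
        raise EDFFormatError(f"unreadable {what} field: {raw!r}") from exc


def read_edf(path) -> RawEDF:
    """Read an EDF/EDF+ file, returning µV-scaled signals."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER_LEN)
        if len(head) < _HEADER_LEN:
            raise EDFFormatError("truncated EDF header")
        recording_id = head[88:168].decode("ascii", "replace")
        n_records = int(_parse_float(head[236:244], "number of records"))
        record_dur = _parse_float(head[244:252], "record duration")
        n_sig = int(_parse_float(head[252:256], "signal count"))
        if n_sig <= 0:
            raise EDFFormatError("no signals in file")

        sig_head = fh.read(n_sig * _SIGNAL_HEADER_LEN)

        def col(offset: int, width: int) -> list[bytes]:
            base = offset * n_sig
            return [sig_head[base + i * width : base + (i + 1) * width] for i in range(n_sig)]

        labels = [b.decode("ascii", "replace").strip() for b in col(0, 16)]
        dims = [b.decode("ascii", "replace").strip() for b in col(96, 8)]
        phys_min = [_parse_float(b, "physical minimum") for b in col(104, 8)]
        phys_max = [_parse_float(b, "physical maximum") for b in col(112, 8)]
        dig_min = [_parse_float(b, "digital minimum") for b in col(120, 8)]
        dig_max = [_parse_float(b, "digital maximum") for b in col(128, 8)]
        spr = [int(_parse_float(b, "samples per record")) for b in col(216, 8)]

        if len(set(spr)) != 1:
            raise EDFFormatError("channels with differing sampling rates are unsupported")
        payload = np.frombuffer(fh.read(2 * n_sig * spr[0] * n_records), dtype="<i2")

    if record_dur <= 0:
        raise EDFFormatError("non-positive record duration")
    fs = spr[0] / record_dur

    digital = payload.reshape(n_records, n_sig, spr[0]).transpose(1, 0, 2).reshape(n_sig, -1)
    data = np.empty(digital.shape, dtype=float)
    for i in range(n_sig):
        if dig_max[i] == dig_min[i]:
            raise EDFFormatError(f"channel {labels[i]!r} has a degenerate digital range")
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (digital[i] - dig_min[i]) * gain + phys_min[i]
        dim = dims[i].lower()
        if dim not in ("uv", "µv", ""):
            warnings.warn(
                f"channel {labels[i]!r} has physical dimension {dims[i]!r}; assuming microvolts",
                stacklevel=2,
            )

    start_h = 0.0
    m = re.search(r"age_h=([0-9.eE+-]+)", recording_id)
    if m:
        start_h = float(m.group(1))
    m = re.search(r"ns=(\d+)", recording_id)
    if m:
        data = data[:, : int(m.group(1))]

    return RawEDF(labels=labels, fs=fs, data=data, start_h=start_h)
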