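"""Recording containers, epoch selection, artifact masking and the 2-channel montage.

Conventions: seconds from record start internally, hours after birth at
interfaces, half-open ``[start, end)`` intervals throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .edf import EDFFormatError, RawEDF, read_edf, write_edf

__all__ = [
    "MONTAGE",
    "EEGRecording",
    "EpochSelection",
    "SeizureAnnotation",
    "EpochSelectionError",
    "MontageError",
    "read_eeg",
    "write_eeg",
    "select_epoch",
    "mask_artifacts",
    "to_aeeg_montage",
    "read_artifact_csv",
    "read_seizure_csv",
]

#: Neonatal 10:20 electrode set (O1/P3 and O2/P4 are alternative posterior sites).
MONTAGE = ("F3", "F4", "C3", "C4", "Cz", "T3", "T4", "O1", "O2", "P3", "P4")

#: Bipolar derivations used by the 2-channel (aEEG-style) analysis.
AEEG_CHANNELS = ("F3-C3", "F4-C4")


class EpochSelectionError(RuntimeError):
    pass


class MontageError(EDFFormatError):
    pass


@dataclass
class EEGRecording:
    """Multichannel EEG in µV with an artifact mask.

    ``artifact_intervals`` are half-open ``(start_s, end_s)`` spans, in seconds
    from the start of this record, flagged unusable for quantitative analysis.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    age_at_start_h: float = 0.0
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        dur = self.duration_s
        for start, end in self.artifact_intervals:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(f"artifact interval ({start}, {end}) outside record [0, {dur})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def sample_mask(self) -> np.ndarray:
        """Boolean per-sample mask, ``True`` where the signal is usable."""
        mask = np.ones(self.n_samples, dtype=bool)
        for start, end in self.artifact_intervals:
            i = int(np.floor(start * self.fs))
            j = int(np.ceil(end * self.fs))
            mask[max(i, 0) : min(j, self.n_samples)] = False
        return mask

    def usable_fraction(self, start_s: float = 0.0, end_s: float | None = None) -> float:
        mask = self.sample_mask()
        i = int(round(start_s * self.fs))
        j = self.n_samples if end_s is None else int(round(end_s * self.fs))
        window = mask[i:j]
        return float(window.mean()) if window.size else 0.0


@dataclass(frozen=True)
class EpochSelection:
    """A selected analysis window, in hours after birth."""

    start_age_h: float
    duration_s: float = 3600.0
    usable_fraction: float = 1.0

    @property
    def end_age_h(self) -> float:
        return self.start_age_h + self.duration_s / 3600.0


@dataclass(frozen=True)
class SeizureAnnotation:
    """Electrographic seizure events as (start_h, end_h) after birth."""

    events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for start, end in self.events:
            if end <= start:
                raise ValueError(f"seizure event ({start}, {end}) has non-positive duration")
            if (end - start) * 3600.0 < 10.0 - 1e-9:
                raise ValueError("seizure events must last at least 10 s")

    @property
    def first_onset_h(self) -> float | None:
        return min((s for s, _ in self.events), default=None)


_LABEL_RE = re.compile(r"^(?:EEG\s+)?([A-Za-z]{1,2}[0-9z]{1,2})(?:[- ]?(?:REF|LE|AVG|A1|A2))?$", re.I)

_CANON = {name.upper(): name for name in MONTAGE}


def normalize_label(raw: str) -> str | None:
    """Map an EDF channel label (e.g. ``'EEG F3-REF'``) to its montage name."""
    m = _LABEL_RE.match(raw.strip())
    if not m:
        return None
    return _CANON.get(m.group(1).upper())


def read_eeg(path, artifact_intervals: list[tuple[float, float]] | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` with montage-normalized labels."""
    raw: RawEDF = read_edf(path)
    labels, rows = [], []
    for lab, row in zip(raw.labels, raw.data):
        canon = normalize_label(lab)
        if canon is not None:
            labels.append(canon)
            rows.append(row)
    if len(labels) < 2:
        unknown = [lab for lab in raw.labels if normalize_label(lab) is None]
        raise MontageError(
            f"fewer than 2 montage channels found; unrecognized labels: {unknown}"
        )
    return EEGRecording(
        channel_labels=labels,
        fs=raw.fs,
        data=np.asarray(rows),
        age_at_start_h=raw.start_h,
        artifact_intervals=list(artifact_intervals or []),
    )


def write_eeg(path, rec: EEGRecording) -> None:
    """Write a recording to EDF (artifact intervals go to a side-car CSV, not EDF)."""
    write_edf(path, rec.data, rec.fs, rec.channel_labels, start_h=rec.age_at_start_h)


def select_epoch(
    rec: EEGRecording,
    seizures: SeizureAnnotation | None = None,
    max_age_h: float = 12.0,
    guard_h: float = 1.0,
    min_usable: float = 0.5,
    duration_s: float = 3600.0,
    step_s: float = 60.0,
) -> EpochSelection:
    """Earliest analysis window of ``duration_s`` satisfying the study rule.

    The window must end before ``max_age_h`` hours of age, end at least
    ``guard_h`` hours before the first seizure onset, and have at least
    ``min_usable`` non-artifact samples.  Candidate starts are scanned forward
    in ``step_s`` steps; the first qualifying window wins.
    """
    if rec.duration_s < duration_s:
        raise EpochSelectionError(
            f"record ({rec.duration_s:.0f} s) shorter than requested epoch ({duration_s:.0f} s)"
        )
    first_onset = seizures.first_onset_h if seizures else None
    failures = {"age": 0, "seizure_guard": 0, "usable": 0}
    start = 0.0
    while start + duration_s <= rec.duration_s + 1e-9:
        end_age = rec.age_at_start_h + (start + duration_s) / 3600.0
        if end_age > max_age_h + 1e-9:
            failures["age"] += 1
        elif first_onset is not None and end_age > first_onset - guard_h + 1e-9:
            failures["seizure_guard"] += 1
        else:
            usable = rec.usable_fraction(start, start + duration_s)
            if usable + 1e-12 >= min_usable:
                return EpochSelection(
                    start_age_h=rec.age_at_start_h + start / 3600.0,
                    duration_s=duration_s,
                    usable_fraction=usable,
                )
            failures["usable"] += 1
        start += step_s
    reason = max(failures, key=failures.get)
    raise EpochSelectionError(
        "no qualifying epoch; candidate windows rejected by constraint "
        f"counts {failures} (dominant: {reason})"
    )


def mask_artifacts(rec: EEGRecording, epoch: EpochSelection) -> EEGRecording:
    """Crop the record to the epoch, carrying artifact intervals along.

    Downstream estimators consult :meth:`EEGRecording.sample_mask` and skip
    short-time windows overlapping any masked span.
    """
    offset_s = (epoch.start_age_h - rec.age_at_start_h) * 3600.0
    if offset_s < -1e-6 or offset_s + epoch.duration_s > rec.duration_s + 1e-6:
        raise ValueError("epoch lies outside the record")
    i = int(round(offset_s * rec.fs))
    j = i + int(round(epoch.duration_s * rec.fs))
    cropped: list[tuple[float, float]] = []
    for start, end in rec.artifact_intervals:
        s = max(start - offset_s, 0.0)
        e = min(end - offset_s, epoch.duration_s)
        if e > s:
            cropped.append((s, e))
    out = EEGRecording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        data=rec.data[:, i:j].copy(),
        age_at_start_h=epoch.start_age_h,
        artifact_intervals=cropped,
    )
    if not out.sample_mask().any():
        raise EpochSelectionError("epoch is entirely masked by artifacts")
    return out


def to_aeeg_montage(rec: EEGRecording) -> EEGRecording:
    """Bipolar 2-channel derivation: F3−C3 (left) and F4−C4 (right)."""
    try:
        idx = {name: rec.channel_labels.index(name) for name in ("F3", "C3", "F4", "C4")}
    except ValueError as exc:
        missing = [n for n in ("F3", "C3", "F4", "C4") if n not in rec.channel_labels]
        raise MontageError(f"electrodes required for the 2-channel montage missing: {missing}") from exc
    data = np.vstack(
        [
            rec.data[idx["F3"]] - rec.data[idx["C3"]],
            rec.data[idx["F4"]] - rec.data[idx["C4"]],
        ]
    )
    return replace(rec, channel_labels=list(AEEG_CHANNELS), data=data)


def _read_interval_csv(path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "onset_s" in cols:
        onset = df[cols["onset_s"]].to_numpy(dtype=float)
    elif "onset_h" in cols:
        onset = df[cols["onset_h"]].to_numpy(dtype=float) * 3600.0
    else:
        raise ValueError(f"{path}: need an 'onset_s' or 'onset_h' column")
    if "duration_s" not in cols:
        raise ValueError(f"{path}: need a 'duration_s' column")
    dur = df[cols["duration_s"]].to_numpy(dtype=float)
    labels = df[cols["label"]].astype(str) if "label" in cols else ["" for _ in onset]
    return [(float(o), float(o + d), str(lab)) for o, d, lab in zip(onset, dur, labels)]


def read_artifact_csv(path) -> list[tuple[float, float]]:
    """Artifact intervals in seconds from record start (columns onset_s|onset_h, duration_s)."""
    return [(s, e) for s, e, _ in _read_interval_csv(path)]


def read_seizure_csv(path) -> SeizureAnnotation:
    """Seizure events; onsets interpreted as hours after birth if given as onset_h."""
    events = tuple((s / 3600.0, e / 3600.0) for s, e, _ in _read_interval_csv(path))
    return SeizureAnnotation(events=events)
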