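"""Reading, writing and segmenting skin-conductance recordings.

Recordings are uniformly sampled electrodermal-activity (EDA) traces in
micro-Siemens, nominally at 32 Hz, with an optional accelerometer-magnitude
channel in g.  Condition markers assign labels to half-open time intervals
``[start_s, end_s)``; cutting a recording at a set of disjoint exhaustive
markers therefore partitions its samples exactly, with no boundary sample
counted twice.

File formats are plain CSV: recordings carry columns ``time_s, eda_uS``
(optionally ``acc_g``), marker files carry ``subject_id, label, start_s,
end_s``.  Lines starting with ``#`` are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EdaRecording",
    "ConditionMarker",
    "Segment",
    "read_recording",
    "write_recording",
    "read_markers",
    "write_markers",
    "cut_segments",
    "equalize_durations",
]


@dataclass(frozen=True)
class EdaRecording:
    """A uniformly sampled EDA trace.

    Parameters
    ----------
    t0 : float
        Start time in seconds.
    fs : float
        Sampling rate in Hz (nominally 32).
    eda : ndarray
        Conductance in µS.
    acc : ndarray or None
        Accelerometer magnitude in g, same length as ``eda``.
    subject_id : str
        Opaque subject label.
    """

    t0: float
    fs: float
    eda: np.ndarray
    acc: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        eda = np.asarray(self.eda, dtype=float)
        object.__setattr__(self, "eda", eda)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if eda.size == 0:
            raise ValueError("eda trace must be non-empty")
        if not np.all(np.isfinite(eda)):
            raise ValueError("eda trace contains non-finite values")
        if self.acc is not None:
            acc = np.asarray(self.acc, dtype=float)
            if acc.shape != eda.shape:
                raise ValueError("acc channel length must match eda")
            object.__setattr__(self, "acc", acc)

    @property
    def n_samples(self) -> int:
        return self.eda.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class ConditionMarker:
    """A labelled half-open interval ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"marker {self.label!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Segment:
    """A labelled slice of a recording."""

    recording: EdaRecording
    label: str

    @property
    def subject_id(self) -> str:
        return self.recording.subject_id

    @property
    def eda(self) -> np.ndarray:
        return self.recording.eda

    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def duration(self) -> float:
        return self.recording.duration


def read_recording(path: str | Path, fs_expected: float,
                   rtol: float = 1e-3) -> EdaRecording:
    """Read a CSV recording and validate uniform sampling.

    The file must have a header with columns ``time_s`` and ``eda_uS`` and
    may have ``acc_g``.  Timestamps must advance by ``1/fs_expected`` within
    a relative tolerance of 0.1 % per step; the first offending row is named
    in the error otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "eda_uS"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - 1.0 / fs_expected) > rtol / fs_expected)[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise ValueError(
                f"{path.name}: non-uniform sampling at row {row + 1} "
                f"(step {dt[bad[0]]:.6f} s, expected {1.0 / fs_expected:.6f} s)"
            )
    acc = df["acc_g"].to_numpy(dtype=float) if "acc_g" in df.columns else None
    return EdaRecording(
        t0=float(t[0]),
        fs=float(fs_expected),
        eda=df["eda_uS"].to_numpy(dtype=float),
        acc=acc,
        subject_id=str(path.stem),
    )


def write_recording(rec: EdaRecording, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write a recording as CSV (time_s, eda_uS[, acc_g]) to 6 decimals."""
    data = {"time_s": rec.times, "eda_uS": rec.eda}
    if rec.acc is not None:
        data["acc_g"] = rec.acc
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_markers(path: str | Path) -> list[ConditionMarker]:
    """Read a marker CSV (subject_id, label, start_s, end_s)."""
    df = pd.read_csv(path, comment="#")
    for col in ("subject_id", "label", "start_s", "end_s"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    markers = [
        ConditionMarker(label=str(r.label), start_s=float(r.start_s),
                        end_s=float(r.end_s), subject_id=str(r.subject_id))
        for r in df.itertuples()
    ]
    _check_no_overlap(markers)
    return markers


def write_markers(markers: Sequence[ConditionMarker], path: str | Path,
                  header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {"subject_id": m.subject_id, "label": m.label,
             "start_s": m.start_s, "end_s": m.end_s}
            for m in markers
        ]
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _check_no_overlap(markers: Sequence[ConditionMarker]) -> None:
    by_subject: dict[str, list[ConditionMarker]] = {}
    for m in markers:
        by_subject.setdefault(m.subject_id, []).append(m)
    for subject, ms in by_subject.items():
        ms = sorted(ms, key=lambda m: m.start_s)
        for a, b in zip(ms, ms[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping markers for subject {subject!r}: "
                    f"{a.label!r} and {b.label!r}"
                )


def cut_segments(rec: EdaRecording,
                 markers: Sequence[ConditionMarker]) -> list[Segment]:
    """Cut a recording into labelled segments.

    Sample ``i`` (at time ``t0 + i/fs``) belongs to a marker iff
    ``start_s <= t_i < end_s``, so adjacent markers share no samples.
    """
    segments: list[Segment] = []
    t_end = rec.t0 + rec.n_samples / rec.fs
    for m in markers:
        if m.start_s < rec.t0 - 0.5 / rec.fs or m.end_s > t_end + 0.5 / rec.fs:
            raise ValueError(
                f"marker {m.label!r} [{m.start_s}, {m.end_s}) outside "
                f"recording span [{rec.t0}, {t_end})"
            )
        i0 = int(np.ceil((m.start_s - rec.t0) * rec.fs - 1e-9))
        i1 = int(np.ceil((m.end_s - rec.t0) * rec.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        if i1 <= i0:
            raise ValueError(f"marker {m.label!r} contains no samples")
        sub = EdaRecording(
            t0=rec.t0 + i0 / rec.fs,
            fs=rec.fs,
            eda=rec.eda[i0:i1].copy(),
            acc=None if rec.acc is None else rec.acc[i0:i1].copy(),
            subject_id=rec.subject_id,
        )
        segments.append(Segment(recording=sub, label=m.label))
    return segments


def equalize_durations(segments: Sequence[Segment],
                       policy: str = "shortest") -> list[Segment]:
    """Truncate all segments to the shortest one, keeping initial portions.

    Mirrors the study convention of comparing conditions over windows of
    equal length anchored at each condition's start (the shortest interval
    across conditions/subjects sets the window).
    """
    if policy != "shortest":
        raise ValueError(f"unknown policy {policy!r}")
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    n_min = min(s.recording.n_samples for s in segments)
    out = []
    for s in segments:
        rec = s.recording
        if rec.n_samples == n_min:
            out.append(s)
            continue
        sub = EdaRecording(
            t0=rec.t0, fs=rec.fs, eda=rec.eda[:n_min].copy(),
            acc=None if rec.acc is None else rec.acc[:n_min].copy(),
            subject_id=rec.subject_id,
        )
        out.append(Segment(recording=sub, label=s.label))
    return out
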