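"""Low-pass filtering, resampling, and rule-based artifact control.

The filter stage is the standard wearable-EDA cleanup: a first-order
Butterworth low-pass at 0.6 Hz, applied forward-backward so the output is
zero-phase (features stay aligned to condition intervals; the two passes
square the single-pass magnitude response, so the gain at the nominal
cutoff is 0.5 rather than 1/sqrt(2)).

Artifact control is a two-stage screen modelled on rule-based quality
assessment for wrist-worn EDA: per-sample rules (out-of-range values,
implausible one-sample slopes, flatlines) flag suspect intervals, flagged
intervals are cross-checked for coincident accelerometer bursts, and a
deterministic exclusion verdict per segment replaces manual visual
inspection (a segment is dropped when too large a fraction of it is flagged
or when it contains a sustained flatline/zero run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .io_events import ConditionMarker, EdaRecording

__all__ = [
    "ArtifactRules",
    "FlaggedInterval",
    "ArtifactReport",
    "lowpass",
    "resample",
    "detect_artifacts",
]


@dataclass(frozen=True)
class ArtifactRules:
    """Thresholds for the rule-based artifact screen.

    Defaults follow the published rule-of-thumb ranges for wearable EDA:
    conductance outside [0.05, 60] µS, one-sample slopes beyond 10 µS/s,
    and windows of 5 s whose range stays under 0.1 nS are physiologically
    implausible.
    """

    min_valid: float = 0.05        # µS
    max_valid: float = 60.0        # µS
    max_slope: float = 10.0        # µS/s
    flat_window: float = 5.0       # s
    flat_eps: float = 1e-4         # µS
    accel_window: float = 2.0      # s
    max_flagged_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.min_valid < self.max_valid:
            raise ValueError("require 0 < min_valid < max_valid")
        for name in ("max_slope", "flat_window", "flat_eps", "accel_window",
                     "max_flagged_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FlaggedInterval:
    rule: str
    start_s: float
    end_s: float
    accel_coincident: bool = False


@dataclass
class ArtifactReport:
    """Per-sample flags plus the per-segment exclusion verdict."""

    mask: np.ndarray                       # bool, one per sample
    intervals: list[FlaggedInterval]
    excluded: dict[str, bool]              # segment label -> verdict
    flagged_fraction: dict[str, float]

    def to_frame(self, subject_id: str = "") -> pd.DataFrame:
        rows = [
            {"subject_id": subject_id, "rule": iv.rule, "start_s": iv.start_s,
             "end_s": iv.end_s, "accel_coincident": iv.accel_coincident}
            for iv in self.intervals
        ]
        return pd.DataFrame(
            rows, columns=["subject_id", "rule", "start_s", "end_s",
                           "accel_coincident"]
        )


@lru_cache(maxsize=64)
def _butter_sos(order: int, cutoff: float, fs: float) -> np.ndarray:
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass(eda: np.ndarray, fs: float, cutoff: float = 0.6,
            order: int = 1) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward).

    DC gain is exactly 1; the effective amplitude gain at `cutoff` is 0.5
    because the two passes square the -3 dB single-pass response.
    """
    eda = np.asarray(eda, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = _butter_sos(order, float(cutoff), float(fs))
    # filtfilt pads by 3x the filter length per pass; demand enough signal
    padlen = 3 * (2 * order + 1)
    if eda.size <= 3 * padlen:
        raise ValueError(
            f"signal too short for filtering ({eda.size} samples, "
            f"need > {3 * padlen})"
        )
    return signal.sosfiltfilt(sos, eda)


def resample(eda: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased downsampling.

    A zero-phase 8th-order Butterworth at 0.45 * fs_out suppresses content
    above the output Nyquist, then the signal is decimated (integer ratios)
    or linearly interpolated onto the output grid.
    """
    eda = np.asarray(eda, dtype=float)
    if fs_out >= fs_in:
        raise ValueError("fs_out must be below fs_in")
    sos = _butter_sos(8, 0.45 * float(fs_out), float(fs_in))
    smooth = signal.sosfiltfilt(sos, eda)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        return smooth[:: int(round(ratio))]
    t_in = np.arange(eda.size) / fs_in
    t_out = np.arange(int(np.floor(eda.size * fs_out / fs_in))) / fs_out
    return np.interp(t_out, t_in, smooth)


def _runs_from_mask(mask: np.ndarray, fs: float, t0: float,
                    rule: str) -> list[FlaggedInterval]:
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = idx[::2], idx[1::2]
    return [
        FlaggedInterval(rule=rule, start_s=t0 + s / fs, end_s=t0 + e / fs)
        for s, e in zip(starts, ends)
    ]


def detect_artifacts(
    rec: EdaRecording,
    rules: ArtifactRules = ArtifactRules(),
    markers: Sequence[ConditionMarker] | None = None,
) -> ArtifactReport:
    """Flag rule violations and decide per-segment exclusion.

    A sample is flagged when its value leaves [min_valid, max_valid], when
    the one-sample slope exceeds ``max_slope`` in magnitude (both samples
    of the step are flagged), or when it lies in any window of length
    ``flat_window`` whose range is below ``flat_eps``.  If an accelerometer
    channel is present, a flagged interval is marked accelerometer-coincident
    when accelerometer activity exceeds the recording median + 3 MAD within
    +- ``accel_window`` of it.  A segment is excluded when its flagged
    fraction exceeds ``max_flagged_fraction`` or it contains a flat/zero run
    of at least ``flat_window``.
    """
    x = rec.eda
    n = x.size
    fs = rec.fs

    range_mask = (x < rules.min_valid) | (x > rules.max_valid)

    slope = np.abs(np.diff(x)) * fs
    step = slope > rules.max_slope
    slope_mask = np.zeros(n, dtype=bool)
    slope_mask[:-1] |= step
    slope_mask[1:] |= step

    w = max(int(round(rules.flat_window * fs)), 2)
    flat_mask = np.zeros(n, dtype=bool)
    if n >= w:
        view = np.lib.stride_tricks.sliding_window_view(x, w)
        flat_start = (view.max(axis=1) - view.min(axis=1)) < rules.flat_eps
        for s in np.flatnonzero(flat_start):
            flat_mask[s:s + w] = True

    mask = range_mask | slope_mask | flat_mask

    intervals = (
        _runs_from_mask(range_mask, fs, rec.t0, "range")
        + _runs_from_mask(slope_mask, fs, rec.t0, "slope")
        + _runs_from_mask(flat_mask, fs, rec.t0, "flatline")
    )
    intervals.sort(key=lambda iv: (iv.start_s, iv.rule))

    if rec.acc is not None and intervals:
        med = float(np.median(rec.acc))
        mad = float(np.median(np.abs(rec.acc - med)))
        burst = rec.acc > med + 3 * max(mad, 1e-12)
        pad = int(round(rules.accel_window * fs))
        for iv in intervals:
            i0 = max(int(round((iv.start_s - rec.t0) * fs)) - pad, 0)
            i1 = min(int(round((iv.end_s - rec.t0) * fs)) + pad, n)
            iv.accel_coincident = bool(burst[i0:i1].any())

    if markers is None:
        markers = [ConditionMarker(label="__all__", start_s=rec.t0,
                                   end_s=rec.t0 + rec.duration,
                                   subject_id=rec.subject_id)]
    excluded: dict[str, bool] = {}
    fractions: dict[str, float] = {}
    flat_or_zero = flat_mask | (np.abs(x) < rules.min_valid)
    for m in markers:
        i0 = max(int(round((m.start_s - rec.t0) * fs)), 0)
        i1 = min(int(round((m.end_s - rec.t0) * fs)), n)
        seg_mask = mask[i0:i1]
        frac = float(seg_mask.mean()) if i1 > i0 else 0.0
        fractions[m.label] = frac
        long_flat = _longest_run(flat_or_zero[i0:i1]) >= w
        excluded[m.label] = frac > rules.max_flagged_fraction or long_flat

    return ArtifactReport(mask=mask, intervals=intervals,
                          excluded=excluded, flagged_fraction=fractions)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return int((idx[1::2] - idx[::2]).max())
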