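"""Per-segment EDA features and baseline z-standardization.

Four features summarize each subject x condition segment, mirroring the
columns of the study-level tables:

* ``mean_scl`` — mean of the tonic component, µS;
* ``nsscr_count`` — number of non-specific SCR peaks above 0.01 µS;
* ``mean_amplitude`` — mean trough-to-peak amplitude of those peaks, µS
  (0 when there are none, keeping repeated-measures tables complete);
* ``edasymp`` — band power of the signal in the sympathetic 0.045–0.25 Hz
  band after downsampling to 2 Hz, µS².

For between-subject comparisons each feature can be z-standardized against
the subject's own resting baseline: baseline statistics (mean and SD) are
estimated from non-overlapping windows of the baseline segment, so the
z-score expresses a condition value in units of that subject's resting
variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .decompose import Decomposition, ScrEvent, DecomposeParams, decompose, detect_scrs
from .preprocess import resample

__all__ = [
    "FEATURE_COLUMNS",
    "SegmentFeatures",
    "mean_scl",
    "scr_features",
    "edasymp",
    "segment_features",
    "baseline_window_stats",
    "z_standardize",
]

FEATURE_COLUMNS = ("mean_scl", "nsscr_count", "mean_amplitude", "edasymp")

#: Band associated with sympathetic nerve activity, Hz.
SYMPATHETIC_BAND = (0.045, 0.25)


@dataclass(frozen=True)
class SegmentFeatures:
    subject_id: str
    label: str
    mean_scl: float
    nsscr_count: int
    mean_amplitude: float
    edasymp: float
    n_valid_samples: int

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "label": self.label,
            "mean_scl": self.mean_scl,
            "nsscr_count": self.nsscr_count,
            "mean_amplitude": self.mean_amplitude,
            "edasymp": self.edasymp,
            "n_valid_samples": self.n_valid_samples,
        }


def mean_scl(d: Decomposition) -> float:
    """Mean of the tonic component (the SCL summary), µS."""
    if d.tonic.size == 0:
        raise ValueError("empty tonic trace")
    return float(d.tonic.mean())


def scr_features(events: list[ScrEvent]) -> tuple[int, float]:
    """Count of Ns.SCR events and their mean amplitude (0 when none)."""
    if not events:
        return 0, 0.0
    amps = [e.amplitude_uS for e in events]
    return len(events), float(np.mean(amps))


def edasymp(eda: np.ndarray, fs: float,
            band: tuple[float, float] = SYMPATHETIC_BAND,
            fs_target: float = 2.0, nperseg: int = 128,
            normalize: bool = False) -> float:
    """Sympathetic band power of an EDA segment, µS².

    The segment is downsampled to 2 Hz, mean-removed, and its Welch power
    spectral density (Blackman window, ``nperseg``-sample segments, 50 %
    overlap) is integrated over the band by the trapezoid rule.  With
    ``normalize=True`` the band power is divided by total power.
    """
    x = np.asarray(eda, dtype=float)
    if fs > fs_target:
        x = resample(x, fs, fs_target)
    elif fs < fs_target:
        raise ValueError("segment sampled below the 2 Hz analysis rate")
    if x.size < nperseg:
        raise ValueError(
            f"segment too short for spectral analysis: {x.size} samples at "
            f"{fs_target:g} Hz, need >= {nperseg}"
        )
    x = x - x.mean()
    freqs, psd = sps.welch(
        x, fs=fs_target, window="blackman", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    power = float(np.trapezoid(psd[in_band], freqs[in_band]))
    if normalize:
        total = float(np.trapezoid(psd, freqs))
        power = power / total if total > 0 else 0.0
    return power


def segment_features(eda: np.ndarray, fs: float, subject_id: str, label: str,
                     params: DecomposeParams | None = None,
                     decomposition: Decomposition | None = None,
                     min_amplitude: float = 0.01,
                     edasymp_nperseg: int = 128) -> SegmentFeatures:
    """Compute all four features for one segment.

    Decomposition runs per segment (each experimental condition separately);
    a precomputed :class:`Decomposition` may be passed to avoid re-solving.
    """
    d = decomposition if decomposition is not None else decompose(
        eda, fs, params or DecomposeParams())
    events = detect_scrs(d, fs, min_amplitude=min_amplitude)
    count, amp = scr_features(events)
    return SegmentFeatures(
        subject_id=subject_id, label=label,
        mean_scl=mean_scl(d), nsscr_count=count, mean_amplitude=amp,
        edasymp=edasymp(eda, fs, nperseg=edasymp_nperseg),
        n_valid_samples=int(np.asarray(eda).size),
    )


def baseline_window_stats(eda: np.ndarray, fs: float, subject_id: str,
                          window_s: float = 30.0,
                          segment_duration_s: float | None = None,
                          params: DecomposeParams | None = None,
                          min_amplitude: float = 0.01) -> pd.DataFrame:
    """Per-subject baseline statistics from non-overlapping windows.

    The baseline segment is decomposed once, then each feature is evaluated
    on consecutive windows of ``window_s`` seconds: SCL as the windowed
    tonic mean, the SCR count rescaled from the window to
    ``segment_duration_s`` (so its scale matches segment-level counts),
    amplitude as the windowed mean amplitude, and band power with the Welch
    segment length shrunk to the window.  Returns a frame with columns
    ``subject_id, feature, baseline_mean, baseline_sd``.
    """
    x = np.asarray(eda, dtype=float)
    n = x.size
    w = int(round(window_s * fs))
    if w < 2 or n // w < 2:
        raise ValueError(
            f"baseline of subject {subject_id!r} too short: need at least "
            f"two windows of {window_s:g} s"
        )
    seg_dur = segment_duration_s if segment_duration_s is not None else n / fs
    d = decompose(x, fs, params or DecomposeParams())
    events = detect_scrs(d, fs, min_amplitude=min_amplitude)
    nper = int(min(128, max(16, round(window_s * 2.0))))
    rows = []
    for i in range(n // w):
        i0, i1 = i * w, (i + 1) * w
        t0, t1 = i0 / fs, i1 / fs
        win_events = [e for e in events if t0 <= e.peak_time_s < t1]
        count, amp = scr_features(win_events)
        rows.append({
            "mean_scl": float(d.tonic[i0:i1].mean()),
            "nsscr_count": count * seg_dur / window_s,
            "mean_amplitude": amp,
            "edasymp": edasymp(x[i0:i1], fs, nperseg=nper),
        })
    win = pd.DataFrame(rows)
    out = []
    for feat in FEATURE_COLUMNS:
        out.append({
            "subject_id": subject_id, "feature": feat,
            "baseline_mean": float(win[feat].mean()),
            "baseline_sd": float(win[feat].std(ddof=1)),
        })
    return pd.DataFrame(out)


def z_standardize(features: pd.DataFrame, baseline_stats: pd.DataFrame,
                  columns: tuple[str, ...] = FEATURE_COLUMNS) -> pd.DataFrame:
    """Standardize features against per-subject baseline statistics.

    Each feature value x of subject s becomes ``(x - m_s) / sd_s`` with
    ``m_s, sd_s`` that subject's baseline mean and SD for the feature
    (columns ``subject_id, feature, baseline_mean, baseline_sd``).  Adds
    ``z_<feature>`` columns.  A zero or missing baseline SD raises an error
    naming the subject and feature.
    """
    out = features.copy()
    stats = baseline_stats.set_index(["subject_id", "feature"])
    for col in columns:
        zcol = np.empty(len(out))
        for i, row in enumerate(out.itertuples()):
            key = (row.subject_id, col)
            if key not in stats.index:
                raise ValueError(
                    f"no baseline statistics for subject {row.subject_id!r}, "
                    f"feature {col!r}"
                )
            m = float(stats.loc[key, "baseline_mean"])
            sd = float(stats.loc[key, "baseline_sd"])
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(
                    f"zero baseline SD for subject {row.subject_id!r}, "
                    f"feature {col!r}"
                )
            zcol[i] = (getattr(row, col) - m) / sd
        out[f"z_{col}"] = zcol
    return out
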