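"""Seeded synthetic EDA cohorts with ground truth.

The generator emulates the structure of skin-conductance recordings from
single-file walking experiments: a slowly drifting tonic level per subject,
condition-dependent tonic offsets, spontaneous skin-conductance responses
(SCRs) as a Poisson-timed point process convolved with a biexponential
(Bateman) kernel, white measurement noise, and optional motion artifacts
with a synchronized accelerometer burst.  Everything is driven by a single
integer seed through a hierarchical ``numpy`` ``SeedSequence`` so that any
sub-simulation is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_events import ConditionMarker, EdaRecording

__all__ = [
    "ScrKernel",
    "ConditionSpec",
    "SubjectProfile",
    "CohortSpec",
    "GroundTruth",
    "ArtifactTruth",
    "CohortResult",
    "scr_kernel_response",
    "poisson_event_times",
    "simulate_recording",
    "inject_artifacts",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ScrKernel:
    """Biexponential SCR impulse response.

    ``h(t) = gain * (exp(-t/tau_decay) - exp(-t/tau_rise))`` with
    ``0 < tau_rise < tau_decay``; ``h(0) = 0`` and ``h -> 0`` as ``t`` grows.
    Defaults (0.7 s rise, 2.0 s decay) are conventional SCR shape constants.
    """

    tau_rise: float = 0.7
    tau_decay: float = 2.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                "require 0 < tau_rise < tau_decay "
                f"(got {self.tau_rise}, {self.tau_decay})"
            )

    @property
    def peak_lag(self) -> float:
        """Time of the kernel maximum after the driving impulse."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def peak_value(self) -> float:
        t = self.peak_lag
        return self.gain * (math.exp(-t / self.tau_decay)
                            - math.exp(-t / self.tau_rise))

    def normalized(self) -> "ScrKernel":
        """Same shape, gain rescaled so the kernel peak equals 1.

        With a unit-peak kernel an isolated event of amplitude *a* produces
        a phasic deflection whose peak height is exactly *a*.
        """
        base = ScrKernel(self.tau_rise, self.tau_decay, 1.0)
        return ScrKernel(self.tau_rise, self.tau_decay, 1.0 / base.peak_value)


def scr_kernel_response(kernel: ScrKernel, fs: float,
                        duration: float) -> np.ndarray:
    """Sample the kernel on a uniform grid ``t = 0, 1/fs, ...``.

    ``duration >= 5 * tau_decay`` is recommended so the tail is negligible.
    """
    t = np.arange(0.0, duration, 1.0 / fs)
    h = kernel.gain * (np.exp(-t / kernel.tau_decay)
                       - np.exp(-t / kernel.tau_rise))
    return np.maximum(h, 0.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One entry of a condition schedule."""

    label: str
    duration_s: float
    scl_offset: float = 0.0      # additive tonic offset, µS
    rate_mult: float = 1.0       # multiplies the subject's base SCR rate

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("condition duration must be positive")
        if self.rate_mult < 0:
            raise ValueError("rate multiplier must be non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    baseline_scl: float = 6.0    # µS
    drift_slope: float = 0.0     # µS/s
    scr_rate: float = 0.05       # base events/s, scaled per condition
    scr_amp_mean: float = 0.3    # µS
    scr_amp_sd: float = 0.1      # µS
    scr_amp_floor: float = 0.05  # µS, truncation of the amplitude draw
    noise_sd: float = 0.01       # µS

    def __post_init__(self) -> None:
        if self.baseline_scl <= 0:
            raise ValueError("baseline_scl must be positive")
        if self.scr_rate < 0 or self.noise_sd < 0:
            raise ValueError("scr_rate and noise_sd must be non-negative")


@dataclass(frozen=True)
class ArtifactTruth:
    kind: str
    start_s: float
    end_s: float


@dataclass
class GroundTruth:
    """True components behind one simulated recording."""

    events: pd.DataFrame          # label, time_s, peak_time_s, amplitude_uS
    tonic: np.ndarray             # µS, same grid as the recording
    markers: list[ConditionMarker]
    artifacts: list[ArtifactTruth] = field(default_factory=list)


# Minimum spacing between SCR events.  Responses closer than ~2 s merge into
# a single phasic peak once the 0.6 Hz low-pass has smeared them, so 3 s keeps
# planted events resolvable by trough-to-peak detection.
MIN_EVENT_SPACING_S = 3.0


def poisson_event_times(rate: float, duration: float, rng: np.random.Generator,
                        min_spacing: float = MIN_EVENT_SPACING_S) -> np.ndarray:
    """Poisson-timed events with a hard minimum spacing.

    The count is drawn exactly from Poisson(rate * duration); given the
    count, times are order statistics of uniforms on the spacing-shrunk
    interval shifted apart by ``min_spacing``, which preserves the Poisson
    count law while enforcing the refractory gap.  If the drawn count
    cannot fit, it is capped at the largest feasible count.
    """
    if rate <= 0 or duration <= 0:
        return np.array([])
    n = rng.poisson(rate * duration)
    if n == 0:
        return np.array([])
    n_max = int(duration / min_spacing)
    n = min(n, n_max)
    free = duration - (n - 1) * min_spacing
    base = np.sort(rng.uniform(0.0, free, size=n))
    return base + min_spacing * np.arange(n)


def simulate_recording(
    profile: SubjectProfile,
    schedule: Sequence[ConditionSpec],
    kernel: ScrKernel | None = None,
    seed: int | np.random.SeedSequence = 0,
    fs: float = 32.0,
    subject_id: str = "sim",
) -> tuple[EdaRecording, GroundTruth]:
    """Simulate one subject's recording over a condition schedule.

    The signal is ``tonic + phasic + noise`` where the tonic part is the
    baseline level plus a linear drift plus the per-condition offsets
    (piecewise constant on the schedule), the phasic part is the sum of
    Poisson-timed events convolved with the SCR kernel (unit peak, so an
    event's drawn amplitude is the peak height of its isolated response),
    and the noise is white Gaussian.  Identical seeds give bit-identical
    output.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    kernel = (kernel or ScrKernel()).normalized()
    rng = np.random.default_rng(seed)

    total = sum(c.duration_s for c in schedule)
    n = int(round(total * fs))
    t = np.arange(n) / fs

    tonic = profile.baseline_scl + profile.drift_slope * t
    markers: list[ConditionMarker] = []
    rows = []
    driver = np.zeros(n)
    start = 0.0
    for cond in schedule:
        end = start + cond.duration_s
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        tonic[i0:i1] += cond.scl_offset
        markers.append(ConditionMarker(label=cond.label, start_s=start,
                                       end_s=end, subject_id=subject_id))
        times = poisson_event_times(profile.scr_rate * cond.rate_mult,
                                    cond.duration_s, rng)
        for et in times:
            amp = max(rng.normal(profile.scr_amp_mean, profile.scr_amp_sd),
                      profile.scr_amp_floor)
            idx = int(round((start + et) * fs))
            if idx >= n:
                continue
            driver[idx] += amp
            rows.append({
                "label": cond.label,
                "time_s": start + et,
                "peak_time_s": start + et + kernel.peak_lag,
                "amplitude_uS": amp,
            })
        start = end

    h = scr_kernel_response(kernel, fs, duration=8.0 * kernel.tau_decay)
    from scipy.signal import fftconvolve

    phasic = fftconvolve(driver, h)[:n]
    noise = rng.normal(0.0, profile.noise_sd, size=n) if profile.noise_sd > 0 \
        else np.zeros(n)
    eda = tonic + phasic + noise

    events = pd.DataFrame(
        rows, columns=["label", "time_s", "peak_time_s", "amplitude_uS"]
    )
    rec = EdaRecording(t0=0.0, fs=fs, eda=eda,
                       acc=np.full(n, 1.0), subject_id=subject_id)
    return rec, GroundTruth(events=events, tonic=tonic, markers=markers)


def inject_artifacts(
    rec: EdaRecording,
    artifact_spec: Sequence[tuple[str, tuple[float, float]]],
    seed: int | np.random.SeedSequence = 0,
    spike_amplitude: float = 5.0,
    burst_g: float = 2.0,
) -> tuple[EdaRecording, list[ArtifactTruth]]:
    """Overlay wearable-style artifacts on a recording.

    Supported kinds: ``flatline`` (signal frozen at the interval's first
    value), ``spike`` (a step of ``spike_amplitude`` µS entered within one
    sample and held for the interval), ``dropout`` (signal forced to 0 µS,
    emulating electrode-contact loss).  Spike and dropout intervals receive
    a synchronized accelerometer burst, as motion artifacts do on wrist-worn
    devices.  Overlapping intervals are rejected.
    """
    ivals = sorted((iv for _, iv in artifact_spec))
    for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
        if b0 < a1:
            raise ValueError("overlapping artifact intervals")
    rng = np.random.default_rng(seed)
    eda = rec.eda.copy()
    acc = rec.acc.copy() if rec.acc is not None else np.full(rec.n_samples, 1.0)
    truth: list[ArtifactTruth] = []
    for kind, (start, end) in artifact_spec:
        if start < rec.t0 or end > rec.t0 + rec.duration:
            raise ValueError(f"artifact interval [{start}, {end}) outside recording")
        i0 = int(round((start - rec.t0) * rec.fs))
        i1 = int(round((end - rec.t0) * rec.fs))
        if kind == "flatline":
            eda[i0:i1] = eda[i0]
        elif kind == "dropout":
            eda[i0:i1] = 0.0
            acc[i0:i1] += burst_g * (1.0 + 0.2 * rng.standard_normal(i1 - i0))
        elif kind == "spike":
            eda[i0:i1] += spike_amplitude
            acc[i0:i1] += burst_g * (1.0 + 0.2 * rng.standard_normal(i1 - i0))
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
        truth.append(ArtifactTruth(kind=kind, start_s=start, end_s=end))
    out = EdaRecording(t0=rec.t0, fs=rec.fs, eda=eda, acc=acc,
                       subject_id=rec.subject_id)
    return out, truth


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``conditions`` fixes the within-subject design (labels, tonic offsets,
    SCR-rate multipliers, durations); subject-level parameters are drawn
    around the cohort means so between-subject variance is non-zero.  The
    baseline tonic level is Normal(6, 3) µS truncated at 0.5 µS, magnitudes
    in the range typical of palmar recordings.
    """

    n_subjects: int
    conditions: tuple[ConditionSpec, ...]
    seed: int = 0
    fs: float = 32.0
    baseline_mean: float = 6.0
    baseline_sd: float = 3.0
    baseline_floor: float = 0.5
    drift_slope_sd: float = 0.001     # µS/s
    scr_rate: float = 0.05            # events/s
    scr_amp_mean: float = 0.3         # µS
    scr_amp_sd: float = 0.1           # µS
    noise_sd: float = 0.01            # µS
    # idiosyncratic per-subject, per-condition tonic scatter (µS): slow state
    # changes between runs (rest breaks, electrode settling).  Without it the
    # only within-subject variation is the linear drift, a degenerate rank-1
    # covariance no real cohort exhibits.
    subject_effect_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.conditions:
            raise ValueError("need at least one condition")


@dataclass
class CohortResult:
    recordings: list[EdaRecording]
    markers: list[ConditionMarker]
    truth: pd.DataFrame               # per subject x condition ground truth
    ground_truths: dict[str, GroundTruth]


def simulate_cohort(spec: CohortSpec,
                    kernel: ScrKernel | None = None) -> CohortResult:
    """Simulate a full cohort; one recording + markers per subject.

    Returns per-subject recordings, the pooled marker list, and a tidy
    ground-truth table with the true mean tonic level and event count per
    subject x condition.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    recordings, markers, rows = [], [], []
    gts: dict[str, GroundTruth] = {}
    for i, child in enumerate(children):
        sid = f"s{i + 1:03d}"
        draw = np.random.default_rng(child.spawn(1)[0])
        baseline = max(draw.normal(spec.baseline_mean, spec.baseline_sd),
                       spec.baseline_floor)
        drift = draw.normal(0.0, spec.drift_slope_sd)
        profile = SubjectProfile(
            baseline_scl=baseline, drift_slope=drift,
            scr_rate=spec.scr_rate, scr_amp_mean=spec.scr_amp_mean,
            scr_amp_sd=spec.scr_amp_sd, noise_sd=spec.noise_sd,
        )
        schedule = spec.conditions
        if spec.subject_effect_sd > 0:
            jitter = draw.normal(0.0, spec.subject_effect_sd,
                                 size=len(spec.conditions))
            schedule = tuple(
                ConditionSpec(c.label, c.duration_s,
                              c.scl_offset + float(j), c.rate_mult)
                for c, j in zip(spec.conditions, jitter)
            )
        rec, gt = simulate_recording(profile, schedule, kernel=kernel,
                                     seed=child.spawn(2)[1], fs=spec.fs,
                                     subject_id=sid)
        recordings.append(rec)
        markers.extend(gt.markers)
        gts[sid] = gt
        for m in gt.markers:
            i0 = int(round(m.start_s * spec.fs))
            i1 = int(round(m.end_s * spec.fs))
            n_ev = int((gt.events["label"] == m.label).sum())
            rows.append({
                "subject_id": sid, "label": m.label,
                "true_mean_tonic": float(gt.tonic[i0:i1].mean()),
                "true_n_events": n_ev,
            })
    truth = pd.DataFrame(rows)
    return CohortResult(recordings=recordings, markers=markers,
                        truth=truth, ground_truths=gts)
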