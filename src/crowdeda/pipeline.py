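"""End-to-end orchestration: simulate a study, run the analysis chain.

``simulate_study`` builds a synthetic cohort shaped like one of the two
experiments (walking-speed study: baseline + freely chosen speed + four
imposed speeds, 3 min each; oval-density study: eight occupancy conditions).
The planted condition effects take the magnitudes of the published
group-mean tables as their reference pattern, so the synthetic cohorts
carry a realistic monotone arousal gradient without claiming to reproduce
any real subject.

``run_pipeline`` executes preprocess -> decompose -> features -> stats on a
set of recordings with markers: low-pass filter, rule-based artifact screen
with per-segment exclusion, duration equalization to the shortest segment,
per-condition decomposition, the four features, optional baseline
z-standardization, and the omnibus + post-hoc statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import design as design_mod
from .decompose import DecomposeParams, decompose, detect_scrs
from .features import (FEATURE_COLUMNS, baseline_window_stats, edasymp,
                       mean_scl, scr_features, z_standardize)
from .io_events import (ConditionMarker, EdaRecording, cut_segments,
                        equalize_durations, read_markers, read_recording,
                        write_markers, write_recording)
from .preprocess import ArtifactRules, detect_artifacts, lowpass, resample
from .stats import StatReport, analyze_study
from .synthdata import (CohortResult, CohortSpec, ConditionSpec, ScrKernel,
                        simulate_cohort)

log = logging.getLogger("crowdeda")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "STUDY1_CONDITIONS",
    "study2_conditions",
    "study_cohort_spec",
    "simulate_study",
    "run_pipeline",
    "write_study",
    "load_study",
]


# Planted tonic offsets (µS, relative to each subject's baseline level) and
# SCR-rate multipliers for the walking-speed study.  The offsets follow the
# published group-mean pattern: the freely chosen speed is most arousing and
# arousal drops monotonically with imposed speed.
STUDY1_CONDITIONS: tuple[ConditionSpec, ...] = (
    ConditionSpec("baseline", 180.0, 0.0, 1.0),
    ConditionSpec("free", 180.0, 2.0, 1.5),
    ConditionSpec("1.41", 180.0, 0.76, 1.3),
    ConditionSpec("0.86", 180.0, -0.12, 1.0),
    ConditionSpec("0.31", 180.0, -0.68, 0.9),
    ConditionSpec("0.19", 180.0, -1.74, 0.9),
)

# Tonic offsets for the eight oval occupancies, following the published
# mean-SCL gradient across densities (µS, relative to the lowest density).
STUDY2_SCL_OFFSETS = (0.0, 0.19, 0.77, 0.72, 1.37, 1.14, 2.13, 2.32)


def study2_conditions(duration_s: float = 150.0,
                      effect_scale: float = 1.0) -> tuple[ConditionSpec, ...]:
    """Occupancy conditions of the oval study, densest last.

    ``effect_scale`` scales the planted tonic gradient (0 gives a null
    cohort for type-I studies); SCR rate rises mildly with density.
    """
    conds = []
    for n, off in zip(design_mod.STUDY2_OCCUPANCIES, STUDY2_SCL_OFFSETS):
        rate_mult = 1.0 + 0.02 * (n - 4) / 36.0
        conds.append(ConditionSpec(f"n={n}", duration_s,
                                   off * effect_scale, rate_mult))
    return tuple(conds)


def study_cohort_spec(study: str, n_subjects: int, seed: int,
                      fs: float = 32.0, duration_s: float | None = None,
                      effect_scale: float = 1.0) -> CohortSpec:
    if study == "study1":
        conds = STUDY1_CONDITIONS
        if duration_s is not None:
            conds = tuple(ConditionSpec(c.label, duration_s, c.scl_offset,
                                        c.rate_mult) for c in conds)
        if effect_scale != 1.0:
            conds = tuple(ConditionSpec(c.label, c.duration_s,
                                        c.scl_offset * effect_scale,
                                        c.rate_mult) for c in conds)
    elif study == "study2":
        conds = study2_conditions(duration_s or 150.0, effect_scale)
    else:
        raise ValueError(f"unknown study {study!r}")
    return CohortSpec(n_subjects=n_subjects, conditions=conds, seed=seed,
                      fs=fs)


def simulate_study(study: str, n_subjects: int, seed: int,
                   fs: float = 32.0, duration_s: float | None = None,
                   effect_scale: float = 1.0,
                   kernel: ScrKernel | None = None) -> CohortResult:
    spec = study_cohort_spec(study, n_subjects, seed, fs=fs,
                             duration_s=duration_s,
                             effect_scale=effect_scale)
    return simulate_cohort(spec, kernel=kernel)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis chain, JSON-serializable."""

    fs: float = 32.0
    filter_cutoff: float = 0.6      # Hz
    filter_order: int = 1
    decompose_fs: float = 8.0       # decomposition grid; SCRs are < 1 Hz
    rules: ArtifactRules = field(default_factory=ArtifactRules)
    decomposition: DecomposeParams = field(default_factory=DecomposeParams)
    min_amplitude: float = 0.01     # µS, Ns.SCR threshold
    edasymp_nperseg: int = 128
    baseline_label: str | None = "baseline"
    baseline_window_s: float = 30.0
    alpha_normality: float = 0.05
    ks_seed: int = 1234
    circumference: float = design_mod.OVAL_CIRCUMFERENCE_M
    body_depth: float = design_mod.BODY_DEPTH_M
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = ArtifactRules(**d["rules"])
        if "decomposition" in d and isinstance(d["decomposition"], dict):
            dd = dict(d["decomposition"])
            if "kernel" in dd and isinstance(dd["kernel"], dict):
                dd["kernel"] = ScrKernel(**dd["kernel"])
            d["decomposition"] = DecomposeParams(**dd)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: pd.DataFrame
    z_features: pd.DataFrame | None
    reports: dict[str, StatReport]
    exclusions: pd.DataFrame
    artifact_intervals: pd.DataFrame
    design_table: pd.DataFrame
    config: PipelineConfig


def run_pipeline(recordings: list[EdaRecording],
                 markers: list[ConditionMarker],
                 config: PipelineConfig = PipelineConfig(),
                 feature_cols: list[str] = list(FEATURE_COLUMNS),
                 compare_labels: list[str] | None = None,
                 run_stats: bool = True) -> PipelineResult:
    """Execute the full analysis chain on recordings + condition markers."""
    by_subject: dict[str, list[ConditionMarker]] = {}
    for m in markers:
        by_subject.setdefault(m.subject_id, []).append(m)

    rows, excl_rows, art_frames = [], [], []
    all_segments = []
    for rec in recordings:
        subj_markers = by_subject.get(rec.subject_id, [])
        if not subj_markers:
            log.warning("subject %s: no markers, skipped", rec.subject_id)
            continue
        report = detect_artifacts(rec, config.rules, subj_markers)
        art = report.to_frame(rec.subject_id)
        art_frames.append(art)
        filtered = lowpass(rec.eda, rec.fs, config.filter_cutoff,
                           config.filter_order)
        frec = EdaRecording(t0=rec.t0, fs=rec.fs, eda=filtered, acc=rec.acc,
                            subject_id=rec.subject_id)
        segments = cut_segments(frec, subj_markers)
        log.info("subject %s: %d segments, %d samples flagged, %d excluded",
                 rec.subject_id, len(segments), int(report.mask.sum()),
                 sum(report.excluded.values()))
        for seg in segments:
            excluded = report.excluded.get(seg.label, False)
            excl_rows.append({
                "subject_id": rec.subject_id, "label": seg.label,
                "excluded": excluded,
                "flagged_fraction": report.flagged_fraction.get(seg.label, 0.0),
            })
            if not excluded:
                all_segments.append(seg)
            else:
                rows.append({
                    "subject_id": rec.subject_id, "label": seg.label,
                    **{c: np.nan for c in FEATURE_COLUMNS},
                    "n_valid_samples": 0, "excluded": True,
                    "exclusion_reason": "artifact rules",
                })

    if all_segments:
        all_segments = equalize_durations(all_segments)
    baseline_stats_frames = []
    for seg in all_segments:
        x = seg.eda
        fs = seg.fs
        if config.decompose_fs < fs:
            xd, fsd = resample(x, fs, config.decompose_fs), config.decompose_fs
        else:
            xd, fsd = x, fs
        d = decompose(xd, fsd, config.decomposition)
        events = detect_scrs(d, fsd, min_amplitude=config.min_amplitude)
        count, amp = scr_features(events)
        rows.append({
            "subject_id": seg.subject_id, "label": seg.label,
            "mean_scl": mean_scl(d), "nsscr_count": count,
            "mean_amplitude": amp,
            "edasymp": edasymp(x, fs, nperseg=config.edasymp_nperseg),
            "n_valid_samples": x.size, "excluded": False,
            "exclusion_reason": "",
        })
        log.info("subject %s / %s: %d SCR events", seg.subject_id, seg.label,
                 count)
        if config.baseline_label is not None and \
                seg.label == config.baseline_label:
            try:
                baseline_stats_frames.append(baseline_window_stats(
                    xd, fsd, seg.subject_id,
                    window_s=config.baseline_window_s,
                    segment_duration_s=x.size / fs,
                    params=config.decomposition,
                    min_amplitude=config.min_amplitude,
                ))
            except ValueError as exc:
                log.warning("subject %s: baseline stats unavailable (%s)",
                            seg.subject_id, exc)

    features = pd.DataFrame(rows)
    z_features = None
    if baseline_stats_frames:
        stats_df = pd.concat(baseline_stats_frames, ignore_index=True)
        # a subject whose baseline SD is zero/undefined for any feature
        # cannot be standardized; drop them from the z table, keep the rest
        bad = set(stats_df.loc[~(stats_df["baseline_sd"] > 0), "subject_id"])
        if bad:
            log.warning("subjects %s dropped from z-standardization "
                        "(degenerate baseline SD)", sorted(bad))
        have = set(stats_df["subject_id"]) - bad
        valid = features[~features["excluded"]]
        if have:
            z_features = z_standardize(
                valid[valid.subject_id.isin(have)],
                stats_df[stats_df.subject_id.isin(have)])

    reports: dict[str, StatReport] = {}
    if run_stats and not features.empty:
        valid = features[~features["excluded"]]
        labels = compare_labels
        if labels is None:
            labels = [l for l in valid["label"].unique()
                      if l != config.baseline_label]
        if len(labels) >= 2:
            reports = analyze_study(valid, feature_cols, labels=labels,
                                    alpha_normality=config.alpha_normality,
                                    ks_seed=config.ks_seed)

    table = design_mod.design_table(circumference=config.circumference,
                                    body_depth=config.body_depth)
    exclusions = pd.DataFrame(
        excl_rows, columns=["subject_id", "label", "excluded",
                            "flagged_fraction"])
    art_frames = [f for f in art_frames if not f.empty]
    artifacts = (pd.concat(art_frames, ignore_index=True) if art_frames
                 else pd.DataFrame(columns=["subject_id", "rule", "start_s",
                                            "end_s", "accel_coincident"]))
    return PipelineResult(features=features, z_features=z_features,
                          reports=reports, exclusions=exclusions,
                          artifact_intervals=artifacts, design_table=table,
                          config=config)


def write_study(cohort: CohortResult, out_dir: str | Path,
                config: PipelineConfig = PipelineConfig()) -> None:
    """Write a simulated cohort as CSV recordings + markers + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash}"
    for rec in cohort.recordings:
        write_recording(rec, out / f"{rec.subject_id}.csv",
                        header_comment=tag)
    write_markers(cohort.markers, out / "markers.csv", header_comment=tag)
    with open(out / "ground_truth.csv", "w") as fh:
        fh.write(f"# {tag}\n")
        cohort.truth.to_csv(fh, index=False)


def load_study(in_dir: str | Path,
               fs: float = 32.0) -> tuple[list[EdaRecording],
                                          list[ConditionMarker]]:
    """Load recordings + markers written by :func:`write_study`."""
    in_dir = Path(in_dir)
    markers = read_markers(in_dir / "markers.csv")
    recordings = [
        read_recording(p, fs_expected=fs)
        for p in sorted(in_dir.glob("s*.csv"))
        if p.name not in ("markers.csv", "ground_truth.csv")
    ]
    return recordings, markers
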