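import logging

import numpy as np
import pytest

from crowdeda.io_events import ConditionMarker, EdaRecording
from crowdeda.synthdata import (CohortSpec, ConditionSpec, SubjectProfile,
                                simulate_recording)

logging.getLogger("crowdeda").setLevel(logging.WARNING)


@pytest.fixture()
def flat_recording() -> EdaRecording:
    """10 s of constant 5 µS at 32 Hz."""
    return EdaRecording(t0=0.0, fs=32.0, eda=np.full(320, 5.0),
                        subject_id="flat")


@pytest.fixture()
def noisy_recording() -> EdaRecording:
    """60 s clean synthetic recording with SCRs, drift and noise."""
    profile = SubjectProfile(baseline_scl=5.0, drift_slope=0.002,
                             scr_rate=0.05, noise_sd=0.01)
    rec, _ = simulate_recording(profile, [ConditionSpec("run", 60.0)],
                                seed=42)
    return rec


@pytest.fixture()
def small_cohort_spec() -> CohortSpec:
    conditions = (
        ConditionSpec("baseline", 70.0, 0.0, 1.0),
        ConditionSpec("A", 70.0, 0.0, 1.0),
        ConditionSpec("B", 70.0, 2.0, 1.0),
    )
    return CohortSpec(n_subjects=3, conditions=conditions, seed=7)
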