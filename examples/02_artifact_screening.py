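"""Rule-based artifact screening with accelerometer coincidence.

Injects an electrode dropout (conductance to 0 uS with a motion burst on
the accelerometer) into a clean synthetic recording and runs the two-stage
screen.  The report lists which rules fired, whether the accelerometer
confirms motion, and the per-segment exclusion verdict that replaces
manual visual inspection.
"""

from crowdeda import detect_artifacts
from crowdeda.io_events import ConditionMarker
from crowdeda.synthdata import (ConditionSpec, SubjectProfile,
                                inject_artifacts, simulate_recording)

profile = SubjectProfile(baseline_scl=5.0, scr_rate=0.05, noise_sd=0.01)
rec, _ = simulate_recording(profile, [ConditionSpec("walk", 60.0)], seed=3)
bad, _ = inject_artifacts(rec, [("dropout", (20.0, 27.0))], seed=1)

markers = [ConditionMarker("walk", 0.0, 60.0, rec.subject_id)]
report = detect_artifacts(bad, markers=markers)

for iv in report.intervals:
    print(f"rule={iv.rule:<9} [{iv.start_s:6.2f}, {iv.end_s:6.2f}) s "
          f"accel_coincident={iv.accel_coincident}")
print(f"flagged fraction: {report.flagged_fraction['walk']:.2%}")
print(f"segment excluded: {report.excluded['walk']}")
print("-> the dropout trips the range and flatline rules, coincides with "
      "the accelerometer burst, and the segment is dropped from analysis.")
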