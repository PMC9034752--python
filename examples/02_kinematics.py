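"""Reach-kinematics preprocessing on simulated trajectories.

Simulates one subject with full minimum-jerk trajectories sampled at 200 Hz,
then extracts movement bounds (10%-of-peak-speed threshold), movement
direction at target distance, reaction times and exclusion flags.
"""

import rotadapt as ra
from rotadapt.kinematics import summarize_experiment
from rotadapt.synthetic_data import SubjectParams, simulate_subject

design = ra.make_design(seed=2)
params = SubjectParams()  # default calibration
records = simulate_subject(design, params, seed=2, trajectories=True,
                           invalid_rate=0.01)

kin = summarize_experiment(records)
print(kin[["trial", "onset_ms", "end_ms", "peak_speed_cm_s",
           "movement_direction_deg", "reaction_time_ms", "valid"]].head(5))

n_excl = int((~kin["valid"]).sum())
print(f"\nexcluded {n_excl}/{len(kin)} trials "
      f"({kin.loc[~kin['valid'], 'exclusion_reason'].value_counts().to_dict()})")
print(f"mean reaction time {kin.reaction_time_ms.mean():.0f} ms, "
      f"mean movement time {(kin.end_ms - kin.onset_ms).mean():.0f} ms")

# Movement direction is reported relative to the target (counterclockwise
# positive), so rotation-phase trials drift toward +30 deg as the subject
# adapts; exclusions follow the non-monotonic-reach and short-reach rules.
epoched = ra.assign_epochs(kin)
print("\nepoch sizes for this subject (before exclusions):")
print(epoched["epoch"].value_counts().sort_index().head(8))
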