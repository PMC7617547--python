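"""Generate a small synthetic reaching cohort and look at its structure.

A cohort bundles, per trial: a triaxial accelerometer trace with a 4-12 Hz
postural tremor burst (large in patients, physiological in controls),
source-level time series for 10 motor ROIs carrying tremor-coherent and
movement-locked band-power structure, and a table of per-trial kinematics.
"""

import numpy as np

from tremornet import SynthConfig, generate_cohort

config = SynthConfig(n_control=3, n_et=3, n_trials_per_subject=8, seed=1)
cohort = generate_cohort(config)

print("Trial table (first rows):")
print(cohort.trials[["subject_id", "group", "uncertainty", "target_size",
                     "reaction_time", "mean_velocity", "tremor_power"]].head(6).round(3))

summary = cohort.trials.groupby("group")[["tremor_power", "mean_velocity"]].mean().round(3)
print("\nGroup means:")
print(summary)

key = next(iter(cohort.accel))
trace = cohort.accel[key]
print(f"\nOne trial ({key[0]}, trial {key[1]}): {trace.n_samples} samples at {trace.fs} Hz,")
print(f"epochs {dict(zip(trace.epoch_labels, np.diff(trace.epoch_marks) / trace.fs))} s")

# Patients carry ~0.85 m/s^2 RMS postural tremor (tremor_power ~ 0.72), while
# controls sit near the 0.19 m/s^2 physiological level (tremor_power ~ 0.036);
# patients also reach slightly slower on average.
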