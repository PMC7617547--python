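"""Movement-locked time-frequency analysis and event-related desynchronization.

Builds one patient's worth of trials, computes multitaper TF maps of the
contralateral SMA channel (4-cycle windows, 0.4 Hz Slepian smoothing),
expresses them as percent change from the rest baseline, and reads out the
low-beta (14-21 Hz) time course. The unbiased band-variance route
(band_power_change) pools power over trials before forming the ratio.
"""

import numpy as np

from tremornet import SynthConfig, generate_cohort, spectral

config = SynthConfig(n_control=0, n_et=1, n_trials_per_subject=30, seed=2,
                     erd_trial_sd=0.0)
cohort = generate_cohort(config)
sid = cohort.subjects[0]
fs = config.fs
freqs = np.arange(4.0, 47.0, 2.0)

# TF-map route on one trial
series = cohort.roi[(sid, 0)]
tf = spectral.tf_transform(series.roi("contra_SMA"), fs, freqs)
rest = series.epoch_slice("rest")
pc = spectral.percent_change(tf, (rest.start / fs + 0.5, rest.stop / fs - 0.5))
low_beta = spectral.band_timecourse(pc, (14, 21))
cue = series.epoch_slice("cue")
sel = (tf.times >= cue.start / fs + 0.4) & (tf.times <= cue.stop / fs - 0.4)
print(f"single-trial TF map: low-beta change in cue = {np.nanmean(low_beta[sel]):.1f} %")

# pooled band-power route over all 30 trials
sigs, slices = [], []
for t in cohort.subject_trials(sid):
    s = cohort.roi[(sid, t)]
    sigs.append(s.roi("contra_SMA"))
    slices.append({e: s.epoch_slice(e) for e in s.epoch_labels})
pooled = spectral.band_power_change(sigs, fs, (14, 21), slices, ["cue", "reach", "hold"])
for epoch, value in pooled.items():
    print(f"pooled low-beta change in {epoch:>5} = {value:.1f} %")

# The patient group's configured low-beta desynchronization is 45% at full
# engagement (cue epoch), shallower in reach/hold where the planning network
# is only partially active; the pooled estimate recovers it within ~2 points.
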