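"""Source-tremor coherence and the subject-overlap statistic.

For each patient, magnitude-squared coherence between each ROI's virtual
channel and the accelerometer tremor signal is pooled over trials in the
4-12 Hz band (restricted to the epochs where tremor is expressed). Each
subject's ROI map is thresholded at their own 85th percentile and the
per-ROI overlap count is tested against Binomial(N, 0.15).
"""

import numpy as np

from tremornet import SynthConfig, generate_cohort, spectral, stats
from tremornet.datatypes import ROI_LABELS

config = SynthConfig(n_control=0, n_et=6, n_trials_per_subject=12, seed=3)
cohort = generate_cohort(config)


def active(signal, series):
    a = series.epoch_slice("posture").start
    b = series.epoch_slice("hold").stop
    return signal[a:b]


subject_maps = []
for sid in cohort.subjects:
    trials = cohort.subject_trials(sid)
    row = []
    for roi in ROI_LABELS:
        sigs = [active(cohort.roi[(sid, t)].roi(roi), cohort.roi[(sid, t)]) for t in trials]
        refs = [active(cohort.tremor_reference[(sid, t)], cohort.roi[(sid, t)]) for t in trials]
        row.append(spectral.band_coherence(sigs, refs, config.fs, (4, 12)).coherence)
    subject_maps.append(row)

overlap = stats.overlap_map(np.asarray(subject_maps), ROI_LABELS, percentile=85)
print(f"{'ROI':>22} {'mean coh':>9} {'overlap':>8} {'p_binom':>8}")
for i, roi in enumerate(ROI_LABELS):
    print(f"{roi:>22} {np.mean([m[i] for m in subject_maps]):>9.3f} "
          f"{overlap.counts[i]:>5}/{overlap.n_subjects} {overlap.p_binom[i]:>8.3f}")

# The contralateral SMA (configured coherence 0.6) collects the overlap count
# with a small binomial tail probability; ROIs without an embedded coupling
# stay near the estimator bias floor and are rarely suprathreshold.
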