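"""Time-frequency PCA: decompose motor-locked oscillations into networks.

Fits the group-level decomposition on a small cohort's averaged, log-scaled,
per-subject Z-normalized time x frequency x ROI tensor, prints the explained
variance split, and back-projects one trial onto the group components.
(Component estimates sharpen with cohort size; the acceptance script runs
the full-scale recovery experiment.)
"""

import numpy as np

from tremornet import SynthConfig, generate_cohort, tfpca
from tremornet.datatypes import TFTensor
from tremornet.pipeline import subject_tensors

config = SynthConfig(n_control=4, n_et=4, n_trials_per_subject=20, seed=4,
                     source_tremor_coherence={}, tremor_amp_posture_et=0.0,
                     tremor_amp_posture_control=0.0)
cohort = generate_cohort(config)
freqs = np.arange(4.0, 47.0, 2.0)

subject_values = []
trial_tensors = {}
ref = None
for sid in cohort.subjects:
    tensor, trials = subject_tensors(cohort, sid, freqs)
    ref = tensor
    subject_values.append(tensor.values)
    trial_tensors[sid] = trials

group = TFTensor(values=np.mean(subject_values, axis=0), freqs=ref.freqs,
                 roi_labels=ref.roi_labels, epoch_bounds=ref.epoch_bounds,
                 normalization="log_z", norm_mean=0.0, norm_sd=1.0)
model = tfpca.fit(group, n_components=4)

shares = 100 * model.explained_variance / model.explained_variance.sum()
print("explained variance share per component:",
      " / ".join(f"{s:.0f}%" for s in shares))
print(f"cumulative explained variance: {100 * model.explained_variance.sum():.1f}%")

for k in range(4):
    cmap = model.component_map(k)
    f_idx, r_idx = np.unravel_index(np.argmax(np.abs(cmap)), cmap.shape)
    print(f"component {k + 1}: strongest loading at {freqs[f_idx]:.0f} Hz, "
          f"{model.roi_labels[r_idx]}")

sid = cohort.subjects[0]
latent = tfpca.backproject(model, trial_tensors[sid][0])
print(f"\nsingle-trial latents for {sid}, trial 0: shape {latent.shape} "
      f"(component x concatenated time)")

# The four components correspond to the embedded motor networks: low-beta
# frontoparietal (dominant share), sensorimotor gamma, prefrontal mu, and the
# upper-beta premotor rebound; single-trial latents feed the quartile-split
# statistics linking network engagement to kinematics.
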