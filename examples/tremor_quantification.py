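"""Quantify tremor from a triaxial accelerometer trace, epoch by epoch.

The chain: zero-phase FIR bandpass to 4-12 Hz, principal-axis projection of
the three axes, multitaper peak-frequency estimation, and RMS amplitude
after re-filtering around the peak +/- 3 Hz.
"""

import numpy as np

from tremornet.datatypes import AccelTrace, EPOCH_ORDER
from tremornet.synth import embed_tremor
from tremornet.tremor import epoch_tremor

fs = 256.0
durations = {"rest": 3.0, "posture": 3.0, "cue": 2.5, "reach": 2.0, "hold": 1.5}
marks = np.concatenate([[0], np.cumsum([int(durations[e] * fs) for e in EPOCH_ORDER])])

# sensor noise plus a 5.8 Hz, 0.85 m/s^2 tremor burst from posture onset
rng = np.random.default_rng(0)
trace = AccelTrace(0.05 * rng.standard_normal((int(marks[-1]), 3)), fs, marks)
trace = embed_tremor(trace, freq=5.8, amp_rms=0.85, seed=rng)

print(f"{'epoch':>8} {'peak (Hz)':>10} {'RMS (m/s^2)':>12}")
for est in epoch_tremor(trace):
    print(f"{est.epoch:>8} {est.peak_freq:>10.2f} {est.amplitude_rms:>12.3f}")

# Rest shows only sensor noise; posture/cue/hold recover the embedded burst:
# peak near 5.8 Hz and amplitude near 0.85 m/s^2 (within a few percent, the
# residual being filter-edge loss and the finite epoch length).
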