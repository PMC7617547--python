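"""Tremor peak frequency and amplitude from triaxial accelerometry.

The estimation chain per epoch: zero-phase FIR bandpass to the 4-12 Hz
tremor band, principal-axis extraction from the 3x3 covariance of the
filtered axes, multitaper peak-frequency estimation on the projection, and
RMS amplitude after re-filtering around the peak +/- 3 Hz.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._signal import fir_bandpass, multitaper_psd
from .datatypes import AccelTrace, TremorEstimate

logger = logging.getLogger(__name__)

TREMOR_BAND = (4.0, 12.0)

#: Tremor is quantified at these epochs: postural hold, post-cue, and the
#: hold after reach termination (plus rest as the reference).
TREMOR_EPOCHS = ("rest", "posture", "cue", "hold")


def dominant_axis_signal(
    trace: AccelTrace, band: tuple[float, float] = TREMOR_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Project the band-filtered triaxial signal onto its principal axis.

    Returns ``(signal, axis)`` where ``axis`` is the unit leading eigenvector
    of the covariance of the filtered axes, sign-fixed so its largest-magnitude
    element is positive, and ``signal`` the projection of the filtered data.
    """
    min_len = 2 * int(round(3 * trace.fs / band[0]))
    if trace.n_samples < min_len:
        raise ValueError(
            f"trace of {trace.n_samples} samples shorter than two filter lengths ({min_len})"
        )
    filtered = fir_bandpass(trace.samples, trace.fs, band[0], band[1], axis=0)
    cov = np.cov(filtered.T)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return filtered @ axis, axis


def peak_frequency(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = TREMOR_BAND,
    taper_density: float = 1.5,
) -> float | None:
    """Peak of the multitaper power spectrum within the tremor band.

    The taper count is ``round(taper_density * duration_s)`` (read as tapers
    per Hz of spectral resolution; minimum 1). Returns None for a flat/zero
    spectrum.
    """
    signal = np.asarray(signal, dtype=np.float64)
    duration = signal.size / fs
    if duration < 2.0:
        raise ValueError(f"signal of {duration:.2f} s shorter than the 2 s minimum")
    if np.all(signal == signal[0]):
        logger.info("peak_frequency: flat signal, no peak")
        return None
    n_tapers = max(1, int(round(taper_density * duration)))
    freqs, psd = multitaper_psd(signal, fs, n_tapers=n_tapers)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        return None
    band_psd = psd[in_band]
    if np.allclose(band_psd, band_psd[0]):
        return None
    return float(freqs[in_band][np.argmax(band_psd)])


def tremor_amplitude(
    trace: AccelTrace,
    peak: float,
    halfwidth: float = 3.0,
    axis: np.ndarray | None = None,
) -> float:
    """RMS (m/s^2) of the dominant-axis signal bandpassed to peak +/- halfwidth."""
    lo, hi = peak - halfwidth, peak + halfwidth
    if lo <= 0:
        raise ValueError(f"band low edge {lo} Hz must be positive")
    if hi >= trace.fs / 2:
        raise ValueError(f"band high edge {hi} Hz exceeds Nyquist")
    if axis is None:
        _, axis = dominant_axis_signal(trace)
    projected = trace.samples @ axis
    narrow = fir_bandpass(projected, trace.fs, lo, hi)
    return float(np.sqrt(np.mean(narrow**2)))


def _epoch_segment(trace: AccelTrace, label: str, min_duration: float = 2.0) -> AccelTrace:
    """Extract one epoch, symmetrically borrowing neighbour samples below 2 s.

    Short epochs (the cue can be 1.5 s at minimal jitter) are padded with
    adjacent samples rather than dropped so spectral estimates stay defined.
    """
    sl = trace.epoch_slice(label)
    a, b = sl.start, sl.stop
    need = int(round(min_duration * trace.fs)) - (b - a)
    if need > 0:
        grow_right = min(need // 2, trace.n_samples - b)
        grow_left = min(need - grow_right, a)
        grow_right = min(need - grow_left, trace.n_samples - b)
        a -= grow_left
        b += grow_right
    seg = trace.samples[a:b]
    marks = np.array([0, seg.shape[0]])
    return AccelTrace(samples=seg, fs=trace.fs, epoch_marks=marks,
                      trial_id=f"{trace.trial_id}:{label}", epoch_labels=(label,))


def epoch_tremor(
    trace: AccelTrace,
    epochs: tuple[str, ...] = TREMOR_EPOCHS,
    band: tuple[float, float] = TREMOR_BAND,
    halfwidth: float = 3.0,
    taper_density: float = 1.5,
) -> list[TremorEstimate]:
    """Run the full tremor chain independently per epoch."""
    out = []
    for label in epochs:
        seg = _epoch_segment(trace, label)
        sig, axis = dominant_axis_signal(seg, band)
        peak = peak_frequency(sig, seg.fs, band, taper_density)
        if peak is None:
            out.append(TremorEstimate(label, np.nan, 0.0, axis))
            continue
        # clamp so peak +/- halfwidth stays inside (0, Nyquist)
        peak_c = float(np.clip(peak, halfwidth + 0.5, seg.fs / 2 - halfwidth - 0.5))
        amp = tremor_amplitude(seg, peak_c, halfwidth, axis=axis)
        out.append(TremorEstimate(label, peak, amp, axis))
    return out


def cohort_tremor_table(cohort) -> pd.DataFrame:
    """Per-trial, per-epoch tremor estimates for a whole cohort."""
    rows = []
    for (subject_id, trial_id), trace in cohort.accel.items():
        for est in epoch_tremor(trace):
            rows.append(
                {
                    "subject_id": subject_id,
                    "trial_id": trial_id,
                    "epoch": est.epoch,
                    "peak_freq": est.peak_freq,
                    "amplitude_rms": est.amplitude_rms,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "trial_id", "epoch", "peak_freq", "amplitude_rms"])
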