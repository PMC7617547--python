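"""Shared low-level signal primitives: FIR filtering, 1/f noise, multitaper PSD."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss


def fir_bandpass(x: np.ndarray, fs: float, lo: float, hi: float, axis: int = -1) -> np.ndarray:
    """Zero-phase windowed-sinc FIR bandpass.

    Filter order scales as 3*fs/lo so the transition band stays proportional
    to the low edge; applied forward-backward for zero phase.
    """
    if not 0 < lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz exceeds Nyquist ({fs / 2} Hz)")
    numtaps = int(round(3 * fs / lo))
    numtaps += 1 - numtaps % 2  # odd length for a type-I filter
    n = np.asarray(x).shape[axis]
    # filtfilt needs padding headroom; shorten the filter on short segments
    max_taps = max(5, (n - 2) // 3)
    if numtaps > max_taps:
        numtaps = max_taps + (1 - max_taps % 2)
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    padlen = min(3 * numtaps, n - 1)
    return sps.filtfilt(taps, [1.0], x, axis=axis, padlen=padlen)


def fft_bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase brick-wall bandpass via the FFT (band edges inclusive).

    Used where an exact band split matters more than time-domain compactness
    (signal synthesis); analysis filtering uses the FIR path.
    """
    if not 0 < lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi})")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(spec * mask, n=n, axis=-1)


def one_over_f_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    exponent: float,
    rms: float = 1.0,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, scaled to ``rms``.

    Returns an array of shape ``shape + (n_samples,)``; channels independent.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1 / fs)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0  # no DC
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def phase_randomized(
    rng: np.random.Generator,
    x: np.ndarray,
    smooth_hz: float = 0.0,
    fs: float | None = None,
) -> np.ndarray:
    """Surrogate with the amplitude spectrum of ``x`` but random Fourier phases.

    With ``smooth_hz`` > 0 the power spectrum is first smoothed with a
    Gaussian kernel of that width. This matters for nearly line-like inputs
    (a narrowband oscillation): an unsmoothed surrogate concentrates all its
    power in one or two Fourier modes and behaves as a constant-phase
    sinusoid, which is trivially coherent with the original. Smoothing turns
    the surrogate into a proper Gaussian process whose phase decorrelates on
    the ~1/smooth_hz timescale, so its expected coherence with ``x`` is the
    estimator bias floor.
    """
    n = x.shape[-1]
    amp = np.abs(np.fft.rfft(x))
    if smooth_hz > 0:
        if fs is None:
            raise ValueError("fs is required when smooth_hz > 0")
        df = fs / n
        sigma_bins = max(smooth_hz / df / 2.355, 1e-6)
        half = int(np.ceil(4 * sigma_bins))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_bins) ** 2)
        k /= k.sum()
        power = np.convolve(amp**2, k, mode="same")
        amp = np.sqrt(power)
    phases = rng.uniform(0, 2 * np.pi, amp.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(amp * np.exp(1j * phases), n=n)


def multitaper_psd(
    x: np.ndarray, fs: float, n_tapers: int | None = None, nw: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Slepian multitaper PSD of a 1-D signal.

    Either ``n_tapers`` (NW inferred as (K+1)/2) or ``nw`` may be given.
    Returns (freqs, psd) with density scaling (integrates to variance).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n_tapers is None and nw is None:
        nw = 4.0
    if n_tapers is None:
        n_tapers = max(1, int(2 * nw - 1))
    if nw is None:
        nw = (n_tapers + 1) / 2.0
    tapers = dpss(n, nw, Kmax=n_tapers)
    if tapers.ndim == 1:
        tapers = tapers[None, :]
    spec = np.fft.rfft(tapers * x[None, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    # one-sided density: double everything except DC (and Nyquist if present)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    return freqs, psd


def raised_cosine_gate(
    n_samples: int, fs: float, intervals: list[tuple[int, int]], ramp: float = 0.2
) -> np.ndarray:
    """0/1 gate over the sample axis with raised-cosine ramps at interval edges.

    ``ramp`` is the transition duration in seconds (<= 250 ms keeps epoch
    transitions faster than the slowest analysis window).
    """
    gate = np.zeros(n_samples)
    half = max(1, int(round(ramp * fs)))
    for a, b in intervals:
        gate[a:b] = 1.0
    if not intervals:
        return gate
    # smooth with a cosine ramp kernel (moving average of raised cosine)
    win = np.hanning(2 * half + 1)
    win /= win.sum()
    return np.convolve(gate, win, mode="same")
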