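"""Movement-locked multitaper time-frequency analysis and band coherence.

The TF transform follows a frequency-adaptive multitaper scheme: the window
at frequency f spans 4 cycles (4/f s), Slepian tapers provide +/-0.4 Hz of
spectral smoothing, and power is evaluated at the exact requested frequency
by direct complex-exponential projection (equivalent to dense zero-padded
FFT interpolation of the tapered segment). The output lies on a fixed 50 ms
time grid so maps from different trials align sample-for-sample.

Coherence uses pooled multitaper cross- and auto-spectra across segments and
trials (the estimator frequency-domain beamformers rely on); per-trial
coherence for trial ranking pools only within-trial segments.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.signal.windows import dpss

from .datatypes import CoherenceResult, TFMap

logger = logging.getLogger(__name__)

HOP_S = 0.05  # fixed output grid


@lru_cache(maxsize=256)
def _dpss_cached(win_len: int, nw: float, k: int) -> np.ndarray:
    tapers = dpss(win_len, nw, Kmax=k)
    if tapers.ndim == 1:
        tapers = tapers[None, :]
    return tapers


def _taper_count(f: float, cycles: float, smoothing: float) -> int:
    # 2*T*W - 1 tapers with T = cycles/f and W = smoothing; the study's
    # parameters (4 cycles, 0.4 Hz) force the single-taper fallback above
    # 1.6 Hz, so most rows use one Slepian.
    t = cycles / f
    return max(1, int(np.floor(2 * t * smoothing - 1)))


def tf_transform_multi(
    signals: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    cycles: float = 4.0,
    smoothing: float = 0.4,
    hop: float = HOP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper TF power for a (n_channels, n_samples) batch.

    Returns ``(values, times)`` with values (n_channels, n_times, n_freqs) in
    PSD units. Power at each frequency is evaluated by direct projection onto
    tapered complex exponentials at exactly that frequency (equivalent to a
    densely zero-padded FFT of each tapered segment). Grid points whose
    window would overrun the signal are NaN; a frequency whose window is
    longer than the whole signal yields an all-NaN row.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    n_ch, n = signals.shape
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("freqs must lie strictly within (0, fs/2)")
    hop_n = max(1, int(round(hop * fs)))
    centers = np.arange(0, n, hop_n)
    times = centers / fs
    values = np.full((n_ch, times.size, freqs.size), np.nan)

    for j, f in enumerate(freqs):
        win_len = int(round(cycles / f * fs))
        if win_len > n:
            logger.info("tf_transform: %.2f Hz window (%d samples) exceeds signal", f, win_len)
            continue
        win_len = max(win_len, 8)
        k = _taper_count(f, cycles, smoothing)
        nw = max((k + 1) / 2.0, (cycles / f) * smoothing, 1.0)
        tapers = _dpss_cached(win_len, float(nw), k)
        t_local = np.arange(win_len) / fs
        carriers = tapers * np.exp(-2j * np.pi * f * t_local)[None, :]  # (k, L)

        half = win_len // 2
        starts = centers - half
        valid = (starts >= 0) & (starts + win_len <= n)
        if not np.any(valid):
            continue
        sv = starts[valid]
        segs = np.lib.stride_tricks.sliding_window_view(signals, win_len, axis=-1)[:, sv]
        coefs = segs @ carriers.T  # (n_ch, m, k)
        power = (np.abs(coefs) ** 2).mean(axis=-1) * 2.0 / fs
        values[:, valid, j] = power
    return values, times


def tf_transform(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    cycles: float = 4.0,
    smoothing: float = 0.4,
    hop: float = HOP_S,
) -> TFMap:
    """Multitaper time-frequency power map (PSD units) of a 1-D signal."""
    if np.ndim(signal) != 1:
        raise ValueError("tf_transform expects a 1-D signal; use tf_transform_multi")
    values, times = tf_transform_multi(signal[None, :], fs, freqs, cycles, smoothing, hop)
    return TFMap(values=values[0], times=times, freqs=np.asarray(freqs, dtype=np.float64),
                 units="power")


def percent_change(tf: TFMap, baseline: tuple[float, float]) -> TFMap:
    """Percent power change relative to the mean over a baseline interval."""
    if tf.units != "power":
        raise ValueError("percent_change expects a power map")
    t0, t1 = baseline
    in_base = (tf.times >= t0) & (tf.times <= t1)
    if not np.any(in_base):
        raise ValueError("baseline interval does not intersect the time axis")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(tf.values[in_base], axis=0)  # per frequency row
    out = np.full_like(tf.values, np.nan)
    ok = np.isfinite(base) & (base > 0)
    if not np.all(ok):
        logger.warning("percent_change: %d rows with zero/NaN baseline dropped", int((~ok).sum()))
    out[:, ok] = 100.0 * (tf.values[:, ok] - base[ok]) / base[ok]
    return TFMap(values=out, times=tf.times, freqs=tf.freqs, units="percent_change")


def band_timecourse(tf: TFMap, band: tuple[float, float]) -> np.ndarray:
    """Mean over the frequency rows inside ``band`` (inclusive edges)."""
    sel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not np.any(sel):
        raise ValueError(f"band {band} does not intersect the frequency axis")
    import warnings

    with warnings.catch_warnings():
        # all-NaN rows (edge windows) stay NaN without complaint
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(tf.values[:, sel], axis=1)


def band_epoch_power(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float],
    epoch_slices: dict[str, slice],
    epochs: Sequence[str],
    trim: float = 0.3,
) -> dict[str, float]:
    """Band-limited variance per epoch (brick-wall split, edges trimmed).

    ``trim`` seconds are cut from each epoch edge so transition ramps and
    filter spreading do not leak across epoch boundaries.
    """
    from ._signal import fft_bandpass

    narrow = fft_bandpass(np.asarray(signal, dtype=np.float64), fs, band[0], band[1])
    k = int(round(trim * fs))
    out = {}
    for e in epochs:
        sl = epoch_slices[e]
        seg = narrow[sl.start + k : sl.stop - k]
        if seg.size < 8:
            seg = narrow[sl]
        out[e] = float(np.var(seg))
    return out


def band_power_change(
    signal: np.ndarray | Sequence[np.ndarray],
    fs: float,
    band: tuple[float, float],
    epoch_slices: dict[str, slice] | Sequence[dict[str, slice]],
    epochs: Sequence[str],
    baseline: str = "rest",
    trim: float = 0.3,
) -> dict[str, float]:
    """Percent change of band-limited power per epoch relative to baseline.

    An event-related (de)synchronization estimate free of the spectral
    smearing of the 4-cycle TF windows: the band variance ratio is formed
    directly. With a list of per-trial signals, power is pooled (averaged)
    across trials before the ratio, which avoids the upward Jensen bias of
    averaging per-trial ratios.
    """
    if isinstance(signal, np.ndarray) and np.ndim(signal) == 1:
        signals = [signal]
        slices = [epoch_slices]
    else:
        signals = list(signal)
        slices = list(epoch_slices)
    wanted = list(dict.fromkeys([*epochs, baseline]))
    acc = {e: 0.0 for e in wanted}
    for sig, sls in zip(signals, slices):
        p = band_epoch_power(sig, fs, band, sls, wanted, trim)
        for e in wanted:
            acc[e] += p[e]
    base = acc[baseline]
    if base == 0:
        raise ValueError("baseline epoch has zero band power")
    return {e: 100.0 * (acc[e] - base) / base for e in epochs}


def _pooled_spectra(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    fs: float,
    seg_len: float,
    n_tapers: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Pooled multitaper Sxx, Syy, Sxy over non-overlapping segments of pairs."""
    ls = int(round(seg_len * fs))
    tapers = dpss(ls, (n_tapers + 1) / 2.0, Kmax=n_tapers)
    if tapers.ndim == 1:
        tapers = tapers[None, :]
    freqs = np.fft.rfftfreq(ls, d=1 / fs)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    sxy = np.zeros(freqs.size, dtype=np.complex128)
    n_segments = 0
    for x, y in pairs:
        m = min(x.size, y.size) // ls
        for i in range(m):
            xs = x[i * ls : (i + 1) * ls]
            ys = y[i * ls : (i + 1) * ls]
            fx = np.fft.rfft(tapers * xs[None, :], axis=-1)
            fy = np.fft.rfft(tapers * ys[None, :], axis=-1)
            sxx += (np.abs(fx) ** 2).mean(axis=0)
            syy += (np.abs(fy) ** 2).mean(axis=0)
            sxy += (fx * np.conj(fy)).mean(axis=0)
            n_segments += 1
    return freqs, sxx, syy, sxy, n_segments


def band_coherence(
    roi_signal: np.ndarray | Sequence[np.ndarray],
    accel_signal: np.ndarray | Sequence[np.ndarray],
    fs: float,
    band: tuple[float, float] = (4.0, 12.0),
    seg_len: float = 2.0,
    n_tapers: int = 3,
    min_segments: int = 4,
) -> CoherenceResult:
    """Band-averaged magnitude-squared coherence.

    Accepts single 1-D signals or matched per-trial lists; cross/auto spectra
    are pooled over all segments and trials before forming the coherence.
    Requires at least ``min_segments`` non-overlapping segments (the estimate
    is trivially 1 from a single segment). The in-band average is weighted by
    the second signal's auto-spectrum, so a narrowband reference (a tremor
    burst) is read at the frequencies where it actually has power rather than
    diluted across the whole band.
    """
    if isinstance(roi_signal, np.ndarray) and roi_signal.ndim == 1:
        roi_list = [roi_signal]
        accel_list = [np.asarray(accel_signal)]
    else:
        roi_list = [np.asarray(s) for s in roi_signal]
        accel_list = [np.asarray(s) for s in accel_signal]
    if len(roi_list) != len(accel_list):
        raise ValueError("trial counts differ between ROI and accelerometer signals")
    for x, y in zip(roi_list, accel_list):
        if x.size != y.size:
            raise ValueError("paired signals must have equal length")

    freqs, sxx, syy, sxy, n_seg = _pooled_spectra(
        list(zip(roi_list, accel_list)), fs, seg_len, n_tapers
    )
    if n_seg < min_segments:
        raise ValueError(f"only {n_seg} segments available; need >= {min_segments}")
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(sxy) ** 2 / (sxx * syy)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    weights = syy[sel]
    coh = float(np.nansum(msc[sel] * weights) / np.sum(weights))

    per_trial = []
    for x, y in zip(roi_list, accel_list):
        f_t, xx, yy, xy, m = _pooled_spectra([(x, y)], fs, seg_len, n_tapers)
        if m == 0:
            per_trial.append(np.nan)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            msc_t = np.abs(xy) ** 2 / (xx * yy)
        sel_t = (f_t >= band[0]) & (f_t <= band[1])
        per_trial.append(float(np.nansum(msc_t[sel_t] * yy[sel_t]) / np.sum(yy[sel_t])))
    return CoherenceResult(
        coherence=coh,
        band=band,
        n_trials=len(roi_list),
        per_trial=np.asarray(per_trial),
        freqs=freqs[sel],
        spectrum=msc[sel],
    )


def regress_out(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares removal of ``reference`` (plus intercept) from ``target``."""
    design = np.column_stack([reference, np.ones_like(reference)])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return target - design @ beta


def auxiliary_coherence(
    roi_trials: Sequence,
    accel_trials: Sequence[np.ndarray],
    reference_roi: str,
    top_fraction: float = 0.5,
    band: tuple[float, float] = (4.0, 12.0),
    seg_len: float = 1.0,
    n_tapers: int = 3,
) -> dict[str, CoherenceResult | None]:
    """Sensitize coherence mapping to weak sources behind a dominant one.

    (1) rank trials by the reference ROI's band coherence with the
    accelerometer and keep the top ``top_fraction``; (2) regress the
    reference channel out of every other ROI in the time domain; (3)
    recompute pooled band coherence per ROI on the residuals. The reference
    ROI itself has zero residual by construction and is reported as None.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    labels = roi_trials[0].roi_labels
    if reference_roi not in labels:
        raise ValueError(f"reference ROI {reference_roi!r} not present")
    ref_signals = [trial.roi(reference_roi) for trial in roi_trials]
    ranking = band_coherence(
        ref_signals, list(accel_trials), roi_trials[0].fs, band, seg_len, n_tapers
    ).per_trial
    n_keep = max(1, int(np.ceil(top_fraction * len(roi_trials))))
    order = np.argsort(-np.nan_to_num(ranking, nan=-1.0), kind="stable")
    keep = np.sort(order[:n_keep])

    fs = roi_trials[0].fs
    results: dict[str, CoherenceResult | None] = {}
    for label in labels:
        if label == reference_roi:
            results[label] = None
            continue
        residuals = []
        accel_keep = []
        resid_power = 0.0
        orig_power = 0.0
        for i in keep:
            trial = roi_trials[i]
            target = trial.roi(label)
            resid = regress_out(target, trial.roi(reference_roi))
            residuals.append(resid)
            accel_keep.append(np.asarray(accel_trials[i]))
            resid_power += float(np.var(resid))
            orig_power += float(np.var(target))
        if orig_power > 0 and resid_power < 1e-10 * orig_power:
            # channel fully explained by the reference (e.g. an exact copy):
            # the residual is numerical noise, which carries no coherence
            results[label] = CoherenceResult(coherence=0.0, band=band, n_trials=len(keep))
            continue
        results[label] = band_coherence(residuals, accel_keep, fs, band, seg_len, n_tapers)
    return results
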