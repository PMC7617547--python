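"""Time-frequency maps, percent change, band coherence, auxiliary regression."""

import numpy as np
import pytest

from tremornet._signal import fft_bandpass, one_over_f_noise
from tremornet.datatypes import ROI_LABELS, RoiSeries, TFMap
from tremornet.spectral import (
    auxiliary_coherence,
    band_coherence,
    band_timecourse,
    percent_change,
    regress_out,
    tf_transform,
)

FS = 256.0
FREQS = np.arange(4.0, 46.0, 2.0)


class TestTfTransform:
    def test_tone_power_concentrates_at_its_row(self):
        t = np.arange(int(12 * FS)) / FS
        sig = np.sin(2 * np.pi * 20.0 * t)
        tf = tf_transform(sig, FS, FREQS)
        mid = np.nanmean(tf.values, axis=0)
        assert FREQS[np.nanargmax(mid)] == 20.0
        # the 4-cycle window has ~f/4 Hz resolution: the mainlobe spans
        # +/-5 Hz at 20 Hz, so concentration is assessed within +/-2 rows
        near = (np.abs(FREQS - 20.0) <= 4.0)
        assert np.nansum(mid[near]) / np.nansum(mid) >= 0.90

    def test_amplitude_step_quarters_power(self):
        rng = np.random.default_rng(0)
        n = int(24 * FS)
        sig = fft_bandpass(rng.standard_normal(n), FS, 14, 21)
        # normalize each half so the realized amplitude step is exactly 0.5
        sig[: n // 2] /= sig[: n // 2].std()
        sig[n // 2 :] /= sig[n // 2 :].std()
        sig[n // 2 :] *= 0.5
        tf = tf_transform(sig, FS, FREQS)
        bt = band_timecourse(tf, (14, 21))
        before = np.nanmean(bt[20 : len(bt) // 2 - 20])
        after = np.nanmean(bt[len(bt) // 2 + 20 : -20])
        assert after / before == pytest.approx(0.25, rel=0.15)

    def test_psd_scaling_matches_white_noise_level(self):
        # Parseval-style check: on white noise the multitaper PSD matches the
        # flat theoretical density 2*sigma^2/fs within 5%
        rng = np.random.default_rng(1)
        sig = rng.standard_normal(int(60 * FS))
        tf = tf_transform(sig, FS, FREQS)
        mean_psd = np.nanmean(tf.values)
        assert mean_psd == pytest.approx(2.0 / FS, rel=0.05)

    def test_time_shift_equivariance_within_one_hop(self):
        rng = np.random.default_rng(2)
        sig = fft_bandpass(rng.standard_normal(int(20 * FS)), FS, 10, 30)
        shift_hops = 7
        shift = int(shift_hops * 0.05 * FS)
        tf_a = tf_transform(sig, FS, FREQS)
        tf_b = tf_transform(np.roll(sig, shift), FS, FREQS)
        a = tf_a.values[40:-40]
        b = tf_b.values[40 + shift_hops : tf_a.values.shape[0] - 40 + shift_hops]
        mask = np.isfinite(a) & np.isfinite(b)
        corr = np.corrcoef(a[mask], b[mask])[0, 1]
        assert corr > 0.98

    def test_window_longer_than_signal_gives_nan_row(self):
        sig = np.random.default_rng(3).standard_normal(int(0.5 * FS))
        tf = tf_transform(sig, FS, np.array([4.0, 40.0]))
        assert np.all(np.isnan(tf.values[:, 0]))  # 1 s window does not fit
        assert np.any(np.isfinite(tf.values[:, 1]))

    def test_frequencies_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="fs/2"):
            tf_transform(np.zeros(1000), FS, np.array([200.0]))


def _flat_map(value=1.0, n_t=50):
    times = np.arange(n_t) * 0.05
    return TFMap(values=np.full((n_t, FREQS.size), value), times=times, freqs=FREQS)


class TestPercentChange:
    def test_unchanged_power_is_zero_percent(self):
        tf = _flat_map(2.0)
        pc = percent_change(tf, (0.0, 1.0))
        np.testing.assert_allclose(pc.values, 0.0, atol=1e-12)

    def test_fifteen_percent_drop(self):
        tf = _flat_map(1.0)
        tf.values[20:] = 0.85
        pc = percent_change(tf, (0.0, 0.5))
        np.testing.assert_allclose(pc.values[25:], -15.0, atol=1e-9)

    def test_doubling_is_plus_hundred(self):
        tf = _flat_map(1.0)
        tf.values[20:] = 2.0
        pc = percent_change(tf, (0.0, 0.5))
        np.testing.assert_allclose(pc.values[25:], 100.0, atol=1e-9)

    def test_baseline_average_is_zero(self):
        rng = np.random.default_rng(4)
        tf = _flat_map(1.0)
        tf.values *= rng.uniform(0.5, 2.0, tf.values.shape)
        pc = percent_change(tf, (0.0, 1.0))
        base = (tf.times >= 0.0) & (tf.times <= 1.0)
        np.testing.assert_allclose(pc.values[base].mean(axis=0), 0.0, atol=1e-9)

    def test_baseline_outside_axis_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(_flat_map(), (100.0, 101.0))


class TestBandTimecourse:
    def test_single_row_band_is_identity(self):
        rng = np.random.default_rng(5)
        tf = _flat_map()
        tf.values = rng.uniform(size=tf.values.shape)
        np.testing.assert_array_equal(band_timecourse(tf, (20, 20)), tf.values[:, FREQS == 20].ravel())

    def test_band_mean_matches_hand_computed(self):
        rng = np.random.default_rng(6)
        tf = _flat_map()
        tf.values = rng.uniform(size=tf.values.shape)
        sel = (FREQS >= 14) & (FREQS <= 21)
        np.testing.assert_allclose(band_timecourse(tf, (14, 21)), tf.values[:, sel].mean(axis=1))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            band_timecourse(_flat_map(), (100, 120))

    def test_erd_additivity_with_flat_baseline(self):
        # percent_change and band averaging commute when the baseline spectrum
        # is flat across the band
        rng = np.random.default_rng(7)
        tf = _flat_map(1.0)
        tf.values *= (1 + 0.3 * np.sin(np.arange(tf.values.shape[0]) / 5))[:, None]
        a = band_timecourse(percent_change(tf, (0, 1)), (14, 21))
        pc_bt = percent_change(
            TFMap(values=band_timecourse(tf, (14, 21))[:, None], times=tf.times,
                  freqs=np.array([17.5])), (0, 1))
        np.testing.assert_allclose(a, pc_bt.values.ravel(), rtol=0.01)


class TestBandCoherence:
    def test_identical_signals_fully_coherent(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(int(30 * FS))
        res = band_coherence(x, x, FS, (4, 12))
        assert res.coherence > 0.999

    def test_independent_noise_below_bias_floor(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(120 * FS))
        y = rng.standard_normal(int(120 * FS))
        res = band_coherence(x, y, FS, (4, 12))
        n_seg = int(120 / 2.0)
        floor = 1.0 / n_seg
        se = floor  # rough scale of the estimator spread at null
        assert res.coherence < floor + 3 * se

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(int(20 * FS))
        y = x + rng.standard_normal(x.size)
        a = band_coherence(x, y, FS, (4, 12)).coherence
        b = band_coherence(1e3 * x, -1e-2 * y, FS, (4, 12)).coherence
        assert a == pytest.approx(b, abs=1e-10)

    def test_too_few_segments_rejected(self):
        x = np.random.default_rng(11).standard_normal(int(3 * FS))
        with pytest.raises(ValueError, match="segments"):
            band_coherence(x, x, FS, (4, 12))

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="equal length"):
            band_coherence(rng.standard_normal(1000), rng.standard_normal(999), FS)


def _coherent_roi_trials(rng, n_trials=12, seconds=10.0):
    n = int(seconds * FS)
    marks = np.linspace(0, n, 6).astype(int)
    trials, accel = [], []
    for _ in range(n_trials):
        base = one_over_f_noise(rng, n, FS, 1.0, shape=(10,))
        ref = fft_bandpass(rng.standard_normal(n), FS, 4, 12)
        series = RoiSeries(base, FS, ROI_LABELS, marks)
        idx = series.roi_labels.index("contra_SMA")
        series.samples[idx] = ref + 0.3 * rng.standard_normal(n)
        # a second ROI carries the reference plus an independent coherent part
        idx2 = series.roi_labels.index("contra_PPC")
        series.samples[idx2] = ref + fft_bandpass(rng.standard_normal(n), FS, 4, 12)
        trials.append(series)
        accel.append(ref)
    return trials, accel


class TestAuxiliaryCoherence:
    def test_reference_copy_has_zero_residual_coherence(self):
        rng = np.random.default_rng(13)
        trials, accel = _coherent_roi_trials(rng)
        for tr in trials:
            tr.samples[tr.roi_labels.index("ipsi_SMA")] = tr.roi("contra_SMA").copy()
        res = auxiliary_coherence(trials, accel, "contra_SMA")
        assert res["contra_SMA"] is None
        assert res["ipsi_SMA"].coherence < 0.05

    def test_regression_removes_only_the_shared_part(self):
        rng = np.random.default_rng(14)
        trials, accel = _coherent_roi_trials(rng)
        raw = band_coherence([t.roi("contra_PPC") for t in trials], accel, FS, (4, 12)).coherence
        res = auxiliary_coherence(trials, accel, "contra_SMA", top_fraction=1.0)
        residual = res["contra_PPC"].coherence
        # residual keeps the independent coherent component but loses the copy
        assert 0.05 < residual < raw

    def test_top_fraction_one_keeps_all_trials(self):
        rng = np.random.default_rng(15)
        trials, accel = _coherent_roi_trials(rng, n_trials=6)
        res = auxiliary_coherence(trials, accel, "contra_SMA", top_fraction=1.0)
        assert res["contra_PPC"].n_trials == 6

    def test_regress_out_removes_scaled_copy(self):
        rng = np.random.default_rng(16)
        ref = rng.standard_normal(5000)
        target = 3.2 * ref + 5.0
        np.testing.assert_allclose(regress_out(target, ref), 0.0, atol=1e-9)
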