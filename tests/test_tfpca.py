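"""tfPCA: tensor preprocessing, SVD fit, back-projection, reconstruction."""

import numpy as np
import pytest

from tremornet.datatypes import ROI_LABELS, TFMap, TFTensor
from tremornet.tfpca import backproject, build_tensor, fit, reconstruct, unnormalize

FREQS = np.arange(4.0, 46.0, 2.0)
N_ROI = 10
EPOCHS = ("rest", "posture", "cue", "reach", "hold")
FRAMES = {"rest": 20, "posture": 20, "cue": 10, "reach": 14, "hold": 10}


def _maps_from_tensor(values):
    """Split a (time, freq, roi) array back into per-ROI per-epoch TFMaps."""
    maps = {}
    cursor = 0
    bounds = {}
    for e in EPOCHS:
        bounds[e] = (cursor, cursor + FRAMES[e])
        cursor += FRAMES[e]
    for r, roi in enumerate(ROI_LABELS):
        maps[roi] = {}
        for e in EPOCHS:
            a, b = bounds[e]
            maps[roi][e] = TFMap(values=values[a:b, :, r],
                                 times=np.arange(b - a) * 0.05, freqs=FREQS)
    return maps


def _random_power(rng, scale=1.0):
    n_t = sum(FRAMES.values())
    return scale * rng.lognormal(0.0, 0.5, (n_t, FREQS.size, N_ROI))


def _tensor(rng, scale=1.0):
    return build_tensor(_maps_from_tensor(_random_power(rng, scale)), ROI_LABELS, EPOCHS)


class TestBuildTensor:
    def test_constant_input_is_all_zero_after_z(self):
        values = np.full((sum(FRAMES.values()), FREQS.size, N_ROI), 3.0)
        t = build_tensor(_maps_from_tensor(values), ROI_LABELS, EPOCHS)
        # the SD floor (1e-12) amplifies float rounding of the mean, so
        # "zero" here means zero at the scale eps/floor
        np.testing.assert_allclose(t.values, 0.0, atol=1e-3)

    def test_scale_invariance_across_subjects(self):
        rng = np.random.default_rng(0)
        power = _random_power(rng)
        a = build_tensor(_maps_from_tensor(power), ROI_LABELS, EPOCHS)
        b = build_tensor(_maps_from_tensor(1e4 * power), ROI_LABELS, EPOCHS)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_unnormalize_recovers_log_power_exactly(self):
        rng = np.random.default_rng(1)
        power = _random_power(rng)
        t = build_tensor(_maps_from_tensor(power), ROI_LABELS, EPOCHS)
        np.testing.assert_allclose(unnormalize(t), np.log(power), atol=1e-9)

    def test_epoch_bounds_partition_time_axis(self):
        rng = np.random.default_rng(2)
        t = _tensor(rng)
        covered = sorted(t.epoch_bounds.values())
        assert covered[0][0] == 0 and covered[-1][1] == t.n_times
        for (a0, b0), (a1, _) in zip(covered, covered[1:]):
            assert b0 == a1

    def test_nonpositive_power_floored(self):
        values = _random_power(np.random.default_rng(3))
        values[0, 0, 0] = 0.0
        t = build_tensor(_maps_from_tensor(values), ROI_LABELS, EPOCHS)
        assert np.isfinite(t.values).all()


def _rank1_tensor(rng, pattern=None, profile=None):
    n_t = sum(FRAMES.values())
    n_v = FREQS.size * N_ROI
    if pattern is None:
        pattern = rng.standard_normal(n_v)
    if profile is None:
        profile = np.sin(np.linspace(0, 4 * np.pi, n_t))
    log_power = 0.5 * np.outer(profile, pattern)
    power = np.exp(log_power).reshape(n_t, FREQS.size, N_ROI)
    return build_tensor(_maps_from_tensor(power), ROI_LABELS, EPOCHS), pattern


class TestFit:
    def test_rank_one_structure_fully_recovered(self):
        rng = np.random.default_rng(4)
        tensor, pattern = _rank1_tensor(rng)
        model = fit(tensor, n_components=2)
        assert model.explained_variance[0] > 0.999
        r = np.corrcoef(model.coefficients[0], pattern)[0, 1]
        assert abs(r) > 0.999

    def test_two_patterns_with_four_to_one_variance(self):
        rng = np.random.default_rng(5)
        n_t = sum(FRAMES.values())
        n_v = FREQS.size * N_ROI
        q, _ = np.linalg.qr(rng.standard_normal((n_v, 2)))
        p1, p2 = q[:, 0], q[:, 1]
        t = np.linspace(0, 4 * np.pi, n_t)
        log_power = 0.4 * (2.0 * np.outer(np.sin(t), p1) + 1.0 * np.outer(np.cos(3 * t), p2))
        power = np.exp(log_power).reshape(n_t, FREQS.size, N_ROI)
        model = fit(build_tensor(_maps_from_tensor(power), ROI_LABELS, EPOCHS), 2)
        ev = model.explained_variance
        assert ev[0] / ev[1] == pytest.approx(4.0, rel=0.15)
        for pat in (p1, p2):
            best = max(abs(np.corrcoef(pat, c)[0, 1]) for c in model.coefficients)
            assert best > 0.95

    def test_matches_covariance_eigendecomposition(self):
        # independent oracle: eigendecomposition of the column covariance
        rng = np.random.default_rng(6)
        tensor = _tensor(rng)
        k = 8
        model = fit(tensor, n_components=k)
        x = tensor.unfold()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(k):
            dot = abs(np.dot(model.coefficients[i], v[:, i]))
            assert dot == pytest.approx(1.0, abs=1e-8)
            assert model.explained_variance[i] == pytest.approx(w[i] / w.sum(), abs=1e-8)

    def test_orthonormal_coefficients_and_uncorrelated_latents(self):
        rng = np.random.default_rng(7)
        model = fit(_tensor(rng), n_components=5)
        gram = model.coefficients @ model.coefficients.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        lat = model.latent
        cov = np.cov(lat)
        off = cov - np.diag(np.diag(cov))
        norm = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.abs(off / norm).max() < 1e-8

    def test_roi_permutation_permutes_coefficients(self):
        rng = np.random.default_rng(8)
        power = _random_power(rng)
        perm = rng.permutation(N_ROI)
        t_a = build_tensor(_maps_from_tensor(power), ROI_LABELS, EPOCHS)
        labels_p = tuple(ROI_LABELS[i] for i in perm)
        maps_p = _maps_from_tensor(power[:, :, perm])
        maps_p = {labels_p[i]: maps_p[ROI_LABELS[i]] for i in range(N_ROI)}
        t_b = build_tensor(maps_p, labels_p, EPOCHS)
        m_a, m_b = fit(t_a, 3), fit(t_b, 3)
        ca = m_a.coefficients.reshape(3, FREQS.size, N_ROI)[:, :, perm]
        cb = m_b.coefficients.reshape(3, FREQS.size, N_ROI)
        for i in range(3):
            assert abs(np.corrcoef(ca[i].ravel(), cb[i].ravel())[0, 1]) > 1 - 1e-9
        np.testing.assert_allclose(np.abs(m_a.latent), np.abs(m_b.latent), atol=1e-8)

    def test_degenerate_tensor_rejected(self):
        values = np.full((sum(FRAMES.values()), FREQS.size, N_ROI), 5.0)
        t = build_tensor(_maps_from_tensor(values), ROI_LABELS, EPOCHS)
        with pytest.raises(ValueError, match="zero variance"):
            fit(t, 2)

    def test_raw_tensor_rejected(self):
        values = _random_power(np.random.default_rng(9))
        t = build_tensor(_maps_from_tensor(values), ROI_LABELS, EPOCHS, normalize=False)
        with pytest.raises(ValueError, match="normalized"):
            fit(t, 2)


class TestBackproject:
    def test_group_tensor_projects_to_fitted_latents(self):
        rng = np.random.default_rng(10)
        tensor = _tensor(rng)
        model = fit(tensor, 4)
        lat = backproject(model, tensor)
        np.testing.assert_allclose(lat, model.latent, atol=1e-9)

    def test_spike_on_one_pattern_appears_in_one_latent(self):
        rng = np.random.default_rng(11)
        tensor = _tensor(rng)
        model = fit(tensor, 3)
        spiked = TFTensor(
            values=tensor.values.copy(), freqs=tensor.freqs, roi_labels=tensor.roi_labels,
            epoch_bounds=tensor.epoch_bounds, normalization="log_z",
            norm_mean=tensor.norm_mean, norm_sd=tensor.norm_sd,
        )
        delta = 5.0
        spiked.values[17] += delta * model.coefficients[1].reshape(FREQS.size, N_ROI)
        lat = backproject(model, spiked)
        assert lat[1, 17] - model.latent[1, 17] == pytest.approx(delta, rel=1e-9)
        assert abs(lat[0, 17] - model.latent[0, 17]) < 1e-9
        assert abs(lat[2, 17] - model.latent[2, 17]) < 1e-9

    def test_zero_tensor_projects_to_negative_column_means(self):
        rng = np.random.default_rng(12)
        tensor = _tensor(rng)
        model = fit(tensor, 3)
        zero = TFTensor(
            values=np.zeros_like(tensor.values), freqs=tensor.freqs,
            roi_labels=tensor.roi_labels, epoch_bounds=tensor.epoch_bounds,
            normalization="log_z", norm_mean=0.0, norm_sd=1.0,
        )
        lat = backproject(model, zero)
        expected = -(model.column_means @ model.coefficients.T)
        for k in range(3):
            np.testing.assert_allclose(lat[k], expected[k], atol=1e-9)

    def test_axis_mismatch_rejected_with_report(self):
        rng = np.random.default_rng(13)
        tensor = _tensor(rng)
        model = fit(tensor, 2)
        other = TFTensor(
            values=tensor.values[:, :-1, :], freqs=tensor.freqs[:-1],
            roi_labels=tensor.roi_labels, epoch_bounds=tensor.epoch_bounds,
            normalization="log_z", norm_mean=0.0, norm_sd=1.0,
        )
        with pytest.raises(ValueError, match="axis mismatch"):
            backproject(model, other)


class TestReconstruct:
    def test_full_rank_error_vanishes(self):
        rng = np.random.default_rng(14)
        tensor, _ = _rank1_tensor(rng)
        model = fit(tensor, 2)
        _, err = reconstruct(model, 2)
        assert err == pytest.approx(0.0, abs=1e-6)

    def test_zero_components_error_is_one(self):
        rng = np.random.default_rng(15)
        model = fit(_tensor(rng), 3)
        approx, err = reconstruct(model, 0)
        assert err == pytest.approx(1.0)
        np.testing.assert_allclose(approx, np.broadcast_to(model.column_means, approx.shape))

    def test_error_equals_one_minus_cumulative_ev(self):
        rng = np.random.default_rng(16)
        model = fit(_tensor(rng), 6)
        for k in range(1, 7):
            _, err = reconstruct(model, k)
            assert err == pytest.approx(1 - model.explained_variance[:k].sum(), abs=1e-12)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(17)
        model = fit(_tensor(rng), 2)
        with pytest.raises(ValueError):
            reconstruct(model, 3)
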