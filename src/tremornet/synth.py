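"""Synthetic reaching-task cohort generator.

Emulates the signal structure the downstream analyses assume: a five-epoch
trial (rest, postural raise, jittered cue, reach, hold), 4-12 Hz postural
tremor bursts on a subject-fixed accelerometer axis, tremor-band cortical
sources phase-coupled to the accelerometer at configurable coherence
(strongest over contralateral SMA), band-limited event-related power changes
in four spatial-spectral networks with a deeper low-beta response in the
patient group, and per-trial kinematics coupled to the realized
desynchronization depth.

Background activity is 1/f Gaussian noise, independent across channels except
for the injected coupled components; volume conduction is deliberately not
modelled (inputs represent beamformed virtual channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._signal import fft_bandpass, one_over_f_noise, phase_randomized
from .config import SynthConfig
from .datatypes import (
    EPOCH_ORDER,
    ROI_LABELS,
    AccelTrace,
    RoiSeries,
    as_epoch_subset,
)

#: Spatial-spectral networks embedded in the source channels. Each entry is
#: (band Hz, ROI subset, per-epoch activation level). Activation 1 applies the
#: full configured power change; negative activation is a post-movement
#: rebound above baseline. The four networks mirror the canonical motor
#: decomposition with temporally distinct engagement: a
#: frontoparietal-sensorimotor low-beta network desynchronizing from cue
#: onset (planning), a movement-locked sensorimotor gamma burst, a
#: preparatory premotor/prefrontal mu network engaged from the postural
#: raise, and an upper-beta premotor network dominated by its post-movement
#: rebound.
NETWORKS: dict[str, dict] = {
    "low_beta_frontoparietal": {
        "band": (14.0, 21.0),
        "rois": (
            "contra_SMA",
            "ipsi_SMA",
            "contra_sensorimotor",
            "ipsi_sensorimotor",
            "contra_PPC",
            "ipsi_PPC",
        ),
        "activation": {"cue": 1.0, "reach": 0.3, "hold": 0.1},
    },
    "gamma_sensorimotor": {
        "band": (30.0, 45.0),
        "rois": ("contra_sensorimotor", "ipsi_sensorimotor"),
        "activation": {"reach": 1.0},
    },
    "mu_premotor": {
        "band": (8.0, 16.0),
        "rois": ("contra_dlPFC", "ipsi_dlPFC"),
        "activation": {"posture": 1.0, "cue": 0.4, "reach": 0.4, "hold": 0.45},
    },
    "upper_beta_premotor": {
        "band": (18.0, 30.0),
        "rois": ("contra_SMA", "ipsi_SMA"),
        "activation": {"hold": -1.0},
    },
}

#: Fixed column order of the trial table (documented external interface).
TRIAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "trial_id",
    "uncertainty",
    "target_size",
    "reaction_time",
    "mean_velocity",
    "path_length",
    "hold_variability",
    "tremor_power",
    "tremor_freq",
    "gt_erd_low_beta",
)


@dataclass
class Cohort:
    """A generated cohort: per-trial traces plus the trial metadata table."""

    accel: dict[tuple[str, int], AccelTrace]
    roi: dict[tuple[str, int], RoiSeries]
    trials: pd.DataFrame
    config: SynthConfig = None
    tremor_reference: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.trials["subject_id"].unique())

    def subject_trials(self, subject_id: str) -> list[int]:
        return list(self.trials.loc[self.trials.subject_id == subject_id, "trial_id"])

    def group_of(self, subject_id: str) -> str:
        return self.trials.loc[self.trials.subject_id == subject_id, "group"].iloc[0]


def _smooth_steps(levels: np.ndarray, fs: float, ramp: float = 0.2) -> np.ndarray:
    """Smooth a per-sample step function with a raised-cosine kernel (~ramp s)."""
    half = max(1, int(round(ramp * fs / 2)))
    win = np.hanning(2 * half + 1)
    win /= win.sum()
    padded = np.concatenate([np.full(half, levels[0]), levels, np.full(half, levels[-1])])
    return np.convolve(padded, win, mode="same")[half:-half]


def _epoch_intervals(trace_marks: np.ndarray, labels: tuple[str, ...], subset) -> list[tuple[int, int]]:
    out = []
    for i, lab in enumerate(labels):
        if lab in subset:
            out.append((int(trace_marks[i]), int(trace_marks[i + 1])))
    return out


def _apply_band_gain(
    x: np.ndarray, fs: float, band: tuple[float, float], activation: np.ndarray, depth: float
) -> np.ndarray:
    """Scale band-limited power by (1-depth)^activation(t), leaving the rest.

    The band split is an exact FFT brick-wall so the realized in-band variance
    ratio matches (1-depth) without transition-band leakage.
    """
    band_part = fft_bandpass(x, fs, band[0], band[1])
    resid = x - band_part
    amp_gain = np.exp(0.5 * activation * np.log1p(-depth))
    return resid + band_part * amp_gain


def embed_tremor(
    trace: AccelTrace,
    freq: float,
    amp_rms: float,
    epochs=("posture", "cue", "reach", "hold"),
    seed: int | np.random.Generator = 0,
    axis: np.ndarray | None = None,
    mod_depth: float = 0.3,
    phase_diffusion: float = 1.5,
) -> AccelTrace:
    """Add a narrowband tremor oscillation to the selected epochs.

    The oscillation is a ``freq`` Hz carrier with Wiener phase noise
    (``phase_diffusion`` rad^2/s, giving a realistic sub-Hz tremor linewidth
    rather than a deterministic spectral line) under slow (<1.5 Hz) amplitude
    modulation, projected onto a randomly oriented (or supplied) dominant
    axis, and scaled so its RMS over the selected epochs equals ``amp_rms``.
    Other epochs are left unchanged up to the <=200 ms onset/offset ramps.
    """
    if not 4.0 <= freq <= 12.0:
        raise ValueError(f"tremor frequency {freq} Hz outside the 4-12 Hz band")
    if amp_rms < 0:
        raise ValueError("amp_rms must be >= 0")
    epochs = as_epoch_subset(epochs)
    out = trace.copy()
    if amp_rms == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = trace.n_samples
    t = np.arange(n) / trace.fs
    if axis is None:
        axis = rng.standard_normal(3)
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)

    phase_walk = np.cumsum(rng.normal(0.0, np.sqrt(phase_diffusion / trace.fs), n))
    carrier = np.cos(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi) + phase_walk)
    if mod_depth > 0:
        slow = one_over_f_noise(rng, n, trace.fs, exponent=0.0, rms=1.0)
        slow = fft_bandpass(slow, trace.fs, 0.2, 1.4)
        slow = slow / max(slow.std(), 1e-12)
        envelope = 1.0 + mod_depth * np.clip(slow, -1.0, 1.0)
    else:
        envelope = np.ones(n)
    intervals = _epoch_intervals(trace.epoch_marks, trace.epoch_labels, epochs)
    gate_steps = np.zeros(n)
    for a, b in intervals:
        gate_steps[a:b] = 1.0
    gate = _smooth_steps(gate_steps, trace.fs)
    osc = envelope * carrier * gate
    # exact RMS over the gated (un-ramped) target region
    region = gate_steps > 0.5
    current = np.sqrt(np.mean(osc[region] ** 2))
    if current > 0:
        osc *= amp_rms / current
    out.samples = out.samples + osc[:, None] * axis[None, :]
    return out


def embed_coherent_source(
    roi: RoiSeries,
    reference: np.ndarray,
    band: tuple[float, float],
    target_coherence: float,
    roi_label: str,
    seed: int | np.random.Generator = 0,
    epochs=None,
) -> RoiSeries:
    """Couple one ROI channel to a reference signal inside a band.

    Within the selected epochs (default: the whole trace) the channel's band
    content is replaced by a power-matched mixture of the band-filtered
    reference and a phase-randomized surrogate with identical amplitude
    spectrum, with mixing fraction equal to ``target_coherence``. Because the
    two mixture parts share a spectral shape, the magnitude-squared coherence
    with the reference over those epochs approaches the target at every
    frequency in the band. When the reference is itself epoch-gated (a tremor
    burst), pass the matching epochs so coherence is defined where the
    reference lives.
    """
    if not 0 <= target_coherence <= 1:
        raise ValueError(f"target_coherence {target_coherence} outside [0, 1]")
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (roi.n_samples,):
        raise ValueError("reference length must match the ROI series")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = roi.copy()
    idx = out.roi_labels.index(roi_label)
    ch = out.samples[idx]
    n = out.n_samples
    band_part = fft_bandpass(ch, out.fs, band[0], band[1])
    resid = ch - band_part

    if epochs is None:
        gate = np.ones(n)
        active = np.ones(n, dtype=bool)
    else:
        epochs = as_epoch_subset(epochs)
        steps = np.zeros(n)
        for a, b in _epoch_intervals(out.epoch_marks, out.epoch_labels, epochs):
            steps[a:b] = 1.0
        gate = _smooth_steps(steps, out.fs)
        active = steps > 0.5

    p_active = band_part[active].std()
    ref_band = fft_bandpass(reference, out.fs, band[0], band[1])
    if ref_band[active].std() == 0:
        raise ValueError("reference has no power in the requested band")
    r_unit = ref_band / ref_band[active].std()
    surrogate = phase_randomized(rng, ref_band, smooth_hz=1.0, fs=out.fs) * gate
    s_unit = surrogate / max(surrogate[active].std(), 1e-12)
    mix = np.sqrt(target_coherence) * r_unit + np.sqrt(1 - target_coherence) * s_unit
    mix = mix / max(mix[active].std(), 1e-12)
    out.samples[idx] = resid + band_part * (1 - gate) + p_active * mix * gate
    return out


def embed_erd(
    roi: RoiSeries,
    band: tuple[float, float],
    depth: float,
    epochs,
    roi_labels=None,
    ramp: float = 0.2,
) -> RoiSeries:
    """Suppress band-limited power during the selected epochs.

    Band variance inside the epochs becomes (1 - depth) times its baseline
    value, with raised-cosine transitions of ``ramp`` seconds (<= 250 ms).
    """
    if not 0 <= depth < 1:
        raise ValueError(f"depth {depth} outside [0, 1)")
    if band[1] >= roi.fs / 2:
        raise ValueError("band exceeds Nyquist")
    if ramp > 0.25:
        raise ValueError("ramp must be <= 250 ms")
    epochs = as_epoch_subset(epochs)
    out = roi.copy()
    labels = roi.roi_labels if roi_labels is None else tuple(roi_labels)
    intervals = _epoch_intervals(out.epoch_marks, out.epoch_labels, epochs)
    steps = np.zeros(out.n_samples)
    for a, b in intervals:
        steps[a:b] = 1.0
    activation = _smooth_steps(steps, out.fs, ramp)
    for lab in labels:
        idx = out.roi_labels.index(lab)
        out.samples[idx] = _apply_band_gain(out.samples[idx], out.fs, band, activation, depth)
    return out


def min_jerk_velocity(peak_velocity: float, duration: float, fs: float) -> np.ndarray:
    """Minimum-jerk speed profile; mean speed = peak/1.875."""
    n = max(int(round(duration * fs)), 2)
    tau = np.linspace(0.0, 1.0, n)
    shape = 30 * tau**2 - 60 * tau**3 + 30 * tau**4  # peaks at 1.875 for tau=0.5
    return peak_velocity * shape / 1.875


def build_trial_trajectory(
    row: pd.Series, epoch_marks: np.ndarray, fs: float, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """1-D speed and position profiles consistent with a trial-table row.

    The reach follows a minimum-jerk speed profile with the row's mean
    velocity, starting ``reaction_time`` seconds after the go cue (taken as
    reach-epoch start); hold position jitters with SD ``hold_variability``.
    Used for onset/summary validation, not consumed by the spectral chain.
    """
    rng = rng or np.random.default_rng(0)
    n = int(epoch_marks[-1])
    speed = np.zeros(n)
    reach_start = int(epoch_marks[EPOCH_ORDER.index("reach")])
    reach_end = int(epoch_marks[EPOCH_ORDER.index("reach") + 1])
    onset = reach_start + int(round(row.reaction_time * fs))
    move_n = max(reach_end - onset, 2)
    profile = min_jerk_velocity(1.875 * row.mean_velocity, move_n / fs, fs)
    speed[onset : onset + profile.size] = profile[: max(0, n - onset)]
    position = np.cumsum(speed) / fs
    hold = slice(reach_end, n)
    position[hold] = position[reach_end - 1] + rng.normal(0, row.hold_variability, n - reach_end)
    return speed, position


def _trial_epoch_marks(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    durs = dict(config.epoch_durations)
    durs["cue"] = durs["cue"] + rng.uniform(-config.cue_jitter, config.cue_jitter)
    samples = [int(round(durs[lab] * config.fs)) for lab in EPOCH_ORDER]
    return np.concatenate([[0], np.cumsum(samples)])


def _balanced_conditions(n_trials: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    cells = [(u, s) for u in ("high", "low") for s in ("large", "small")]
    reps = -(-n_trials // len(cells))
    seq = (cells * reps)[:n_trials]
    rng.shuffle(seq)
    return seq


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a full cohort of accelerometer traces, ROI series and trials.

    Deterministic given ``config.seed``: per-subject random streams are spawned
    from a single seed sequence, so the cohort is reproducible byte-for-byte.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_subjects = config.n_control + config.n_et
    subject_seeds = root.spawn(n_subjects)

    accel: dict[tuple[str, int], AccelTrace] = {}
    roi_data: dict[tuple[str, int], RoiSeries] = {}
    references: dict[tuple[str, int], np.ndarray] = {}
    rows = []

    ke = config.kinematic_effect_sizes
    for s_idx in range(n_subjects):
        group = "control" if s_idx < config.n_control else "ET"
        subject_id = f"{'C' if group == 'control' else 'P'}{s_idx:02d}"
        rng = np.random.default_rng(subject_seeds[s_idx])

        tremor_freq = float(
            np.clip(rng.normal(config.tremor_freq_mean, config.tremor_freq_sd), 4.0, 12.0)
        )
        tremor_amp = (
            config.tremor_amp_posture_et if group == "ET" else config.tremor_amp_posture_control
        )
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        vel_base = rng.normal(1.0, 0.08)
        rt_base = rng.normal(0.35, 0.03)
        depths = config.erd_depth_et if group == "ET" else config.erd_depth_control

        conditions = _balanced_conditions(config.n_trials_per_subject, rng)
        for k, (uncertainty, target_size) in enumerate(conditions):
            marks = _trial_epoch_marks(config, rng)
            n = int(marks[-1])
            trial_id = k

            # --- accelerometer -------------------------------------------------
            samples = one_over_f_noise(
                rng, n, config.fs, config.noise_exponent, rms=config.accel_noise_rms, shape=(3,)
            ).T
            trace = AccelTrace(samples=samples, fs=config.fs, epoch_marks=marks,
                               trial_id=f"{subject_id}_t{k}")
            amp_trial = tremor_amp * rng.lognormal(-0.005, 0.1)
            before = trace.samples.copy()
            trace = embed_tremor(
                trace, tremor_freq, amp_trial,
                epochs=("posture", "cue", "reach", "hold"),
                seed=rng, axis=axis, mod_depth=config.tremor_mod_depth,
            )
            # pure tremor component on the dominant axis: the coupling reference
            reference = (trace.samples - before) @ axis

            # --- ROI sources ---------------------------------------------------
            roi_samples = one_over_f_noise(
                rng, n, config.fs, config.noise_exponent, rms=1.0, shape=(len(ROI_LABELS),)
            )
            series = RoiSeries(
                samples=roi_samples, fs=config.fs, roi_labels=ROI_LABELS,
                epoch_marks=marks, trial_id=f"{subject_id}_t{k}",
            )
            if group == "ET" and np.any(reference != 0):
                for label, coh in config.source_tremor_coherence.items():
                    if coh > 0:
                        series = embed_coherent_source(
                            series, reference, (4.0, 12.0), coh, label, seed=rng,
                            epochs=("posture", "cue", "reach", "hold"),
                        )

            realized_depths = {}
            for net_name, net in NETWORKS.items():
                base_depth = depths.get(net_name, 0.0)
                d = base_depth + rng.normal(0, config.erd_trial_sd)
                d = float(np.clip(d, -3.0, 0.95))
                realized_depths[net_name] = d
                steps = np.zeros(n)
                for lab, level in net["activation"].items():
                    sl = series.epoch_slice(lab)
                    steps[sl] = level
                activation = _smooth_steps(steps, config.fs)
                for lab in net["rois"]:
                    idx = series.roi_labels.index(lab)
                    series.samples[idx] = _apply_band_gain(
                        series.samples[idx], config.fs, net["band"], activation, d
                    )

            # --- kinematics ----------------------------------------------------
            d_lb = realized_depths["low_beta_frontoparietal"]
            d_lb_base = depths.get("low_beta_frontoparietal", 0.0)
            rt = rt_base + (ke["rt_small_target"] if target_size == "small" else 0.0)
            rt += ke["rt_high_uncertainty"] if uncertainty == "high" else 0.0
            rt += rng.normal(0, 0.04)
            rt = max(rt, 0.08)
            vel = vel_base
            vel += ke["vel_small_target"] if target_size == "small" else 0.0
            vel += ke["vel_high_uncertainty"] if uncertainty == "high" else 0.0
            vel += ke["vel_et_offset"] if group == "ET" else 0.0
            vel -= config.latent_kinematic_coupling * (d_lb - d_lb_base)
            vel += rng.normal(0, 0.05)
            vel = max(vel, 0.1)
            reach_dur = (marks[4] - marks[3]) / config.fs
            path = vel * reach_dur * rng.normal(1.0, 0.03)
            hold_var = abs(0.008 + 0.004 * amp_trial + rng.normal(0, 0.002))

            key = (subject_id, trial_id)
            accel[key] = trace
            roi_data[key] = series
            references[key] = reference
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "trial_id": trial_id,
                    "uncertainty": uncertainty,
                    "target_size": target_size,
                    "reaction_time": rt,
                    "mean_velocity": vel,
                    "path_length": path,
                    "hold_variability": hold_var,
                    "tremor_power": amp_trial**2,
                    "tremor_freq": tremor_freq,
                    "gt_erd_low_beta": d_lb,
                }
            )

    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return Cohort(accel=accel, roi=roi_data, trials=trials, config=config,
                  tremor_reference=references)
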