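"""Configuration objects for the synthetic cohort generator and pipeline runs.

Both configs round-trip losslessly through YAML so a run can be reproduced
from its config file and seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datatypes import EPOCH_ORDER, ROI_LABELS

# Analysis bands (Hz). Low and upper beta deliberately overlap: they are
# distinct functional sub-bands, not a partition of 14-30 Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "tremor": (4.0, 12.0),
    "mu": (8.0, 16.0),
    "low_beta": (14.0, 21.0),
    "upper_beta": (18.0, 30.0),
    "gamma": (30.0, 45.0),
}


def _default_epoch_durations() -> dict[str, float]:
    # Task structure: eyes-open rest, postural raise, directional cue
    # (jittered), centre-out reach, sustained hold.
    return {"rest": 3.0, "posture": 3.0, "cue": 2.5, "reach": 2.0, "hold": 1.5}


def _default_coherence() -> dict[str, float]:
    # Tremor-band source coupling targets per ROI for patients: strongest over
    # contralateral SMA, secondary sources in prefrontal, parietal and
    # cerebellar ROIs, none elsewhere.
    coh = {label: 0.0 for label in ROI_LABELS}
    coh.update(
        {
            "contra_SMA": 0.6,
            "contra_dlPFC": 0.3,
            "contra_PPC": 0.25,
            "contra_cerebellumVI": 0.2,
            "ipsi_cerebellumVI": 0.2,
        }
    )
    return coh


def _default_erd_control() -> dict[str, float]:
    # Fractional band-power drop (event-related desynchronization) per
    # network for healthy controls; the gamma network is an event-related
    # power increase and carries a negative "depth". Magnitudes are graded so
    # the four networks carry a descending share of motor-locked variance,
    # the dominant one being the low-beta network.
    return {
        "low_beta_frontoparietal": 0.30,
        "gamma_sensorimotor": -0.40,
        "mu_premotor": 0.28,
        "upper_beta_premotor": 0.15,
    }


def _default_erd_et() -> dict[str, float]:
    # Patients show deeper low-beta desynchronization (the 15-point group
    # effect) and a deeper upper-beta premotor response.
    return {
        "low_beta_frontoparietal": 0.45,
        "gamma_sensorimotor": -0.40,
        "mu_premotor": 0.28,
        "upper_beta_premotor": 0.22,
    }


def _default_kinematic_effects() -> dict[str, float]:
    # Additive condition/group offsets, in seconds (rt_*) and units/s (vel_*).
    return {
        "rt_small_target": 0.08,
        "rt_high_uncertainty": 0.02,
        "vel_small_target": -0.05,
        "vel_high_uncertainty": -0.08,
        "vel_et_offset": -0.10,
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic reaching cohort.

    Defaults emulate the study conditions: 4-12 Hz postural tremor at a mean
    of 5.8 Hz, a 0.85 m/s^2 patient amplitude step at posture onset against a
    ~0.19 m/s^2 physiological control tremor, tremor-band source coupling
    strongest over contralateral SMA, and band-limited desynchronization
    networks with a deeper low-beta response in patients.
    """

    n_control: int = 11
    n_et: int = 12
    n_trials_per_subject: int = 20
    fs: float = 256.0
    epoch_durations: dict[str, float] = field(default_factory=_default_epoch_durations)
    cue_jitter: float = 1.0
    tremor_freq_mean: float = 5.8
    tremor_freq_sd: float = 1.6
    tremor_amp_posture_et: float = 0.85
    tremor_amp_posture_control: float = 0.19
    tremor_mod_depth: float = 0.3
    erd_depth_control: dict[str, float] = field(default_factory=_default_erd_control)
    erd_depth_et: dict[str, float] = field(default_factory=_default_erd_et)
    erd_trial_sd: float = 0.12
    source_tremor_coherence: dict[str, float] = field(default_factory=_default_coherence)
    noise_exponent: float = 1.0
    accel_noise_rms: float = 0.05
    kinematic_effect_sizes: dict[str, float] = field(default_factory=_default_kinematic_effects)
    latent_kinematic_coupling: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_control", "n_et", "n_trials_per_subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for label in EPOCH_ORDER:
            if label not in self.epoch_durations:
                raise ValueError(f"epoch_durations missing epoch {label!r}")
            if self.epoch_durations[label] <= 0:
                raise ValueError(f"epoch_durations[{label!r}] must be > 0")
        if self.cue_jitter < 0 or self.cue_jitter >= self.epoch_durations["cue"]:
            raise ValueError("cue_jitter must be in [0, cue duration)")
        if not 4.0 <= self.tremor_freq_mean <= 12.0:
            raise ValueError("tremor_freq_mean must lie in the 4-12 Hz tremor band")
        if self.tremor_freq_sd < 0:
            raise ValueError("tremor_freq_sd must be >= 0")
        if self.tremor_amp_posture_et < 0 or self.tremor_amp_posture_control < 0:
            raise ValueError("tremor amplitudes must be >= 0")
        if not 0 <= self.tremor_mod_depth < 1:
            raise ValueError("tremor_mod_depth must be in [0, 1)")
        # fs must comfortably sample the fastest generated oscillation
        # (gamma network upper edge, 45 Hz): require fs >= 4x.
        if self.fs < 4 * 45.0:
            raise ValueError("fs must be at least 4x the highest generated frequency (45 Hz)")
        for name, depths in (
            ("erd_depth_control", self.erd_depth_control),
            ("erd_depth_et", self.erd_depth_et),
        ):
            for net, d in depths.items():
                if d >= 1:
                    raise ValueError(f"{name}[{net!r}] must be < 1 (fractional power drop)")
        for label, c in self.source_tremor_coherence.items():
            if label not in ROI_LABELS:
                raise ValueError(f"unknown ROI {label!r} in source_tremor_coherence")
            if not 0 <= c <= 1:
                raise ValueError(f"source_tremor_coherence[{label!r}] must be in [0, 1]")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """Full pipeline configuration: generator block plus analysis parameters."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BANDS.items()}
    )
    tf_fmin: float = 4.0
    tf_fmax: float = 46.0
    tf_fstep: float = 2.0
    overlap_percentile: float = 85.0
    cluster_forming_p: float = 0.1
    alpha: float = 0.05
    n_permutations: int = 2000
    n_components: int = 4
    top_fraction: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "synth" in data and isinstance(data["synth"], dict):
            data["synth"] = SynthConfig.from_dict(data["synth"])
        if "bands" in data:
            data["bands"] = {k: tuple(v) for k, v in data["bands"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
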