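"""Core containers shared across the analysis chain.

All containers are light dataclasses around numpy arrays / pandas frames.
Validation happens at construction so downstream code can assume invariants
(finite samples, ordered epoch marks, the fixed 10-ROI layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical task epochs in temporal order.
EPOCH_ORDER: tuple[str, ...] = ("rest", "posture", "cue", "reach", "hold")

#: The fixed motor ROI set: ipsi/contralateral dorsolateral prefrontal cortex,
#: supplementary motor area, sensorimotor cortex, posterior parietal cortex and
#: cerebellum lobule VI (source-level virtual channels).
ROI_LABELS: tuple[str, ...] = (
    "contra_dlPFC",
    "ipsi_dlPFC",
    "contra_SMA",
    "ipsi_SMA",
    "contra_sensorimotor",
    "ipsi_sensorimotor",
    "contra_PPC",
    "ipsi_PPC",
    "contra_cerebellumVI",
    "ipsi_cerebellumVI",
)


def _check_epoch_marks(marks: np.ndarray, n_samples: int, n_epochs: int) -> np.ndarray:
    marks = np.asarray(marks, dtype=np.int64)
    if marks.ndim != 1 or marks.size != n_epochs + 1:
        raise ValueError(
            f"epoch_marks must hold {n_epochs + 1} boundaries, got shape {marks.shape}"
        )
    if np.any(np.diff(marks) <= 0):
        raise ValueError("epoch_marks must be strictly increasing")
    if marks[0] < 0 or marks[-1] > n_samples:
        raise ValueError("epoch_marks must lie within [0, n_samples]")
    return marks


@dataclass
class AccelTrace:
    """One trial of triaxial acceleration (m/s^2).

    ``samples`` is (n_samples, 3); ``epoch_marks`` holds the boundary sample of
    each task epoch (len = len(epoch_labels) + 1, covering the whole trace).
    """

    samples: np.ndarray
    fs: float
    epoch_marks: np.ndarray
    trial_id: str = ""
    epoch_labels: tuple[str, ...] = EPOCH_ORDER

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.epoch_labels = tuple(self.epoch_labels)
        self.epoch_marks = _check_epoch_marks(
            self.epoch_marks, self.samples.shape[0], len(self.epoch_labels)
        )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def epoch_slice(self, label: str) -> slice:
        """Half-open sample range of a named epoch."""
        i = self.epoch_labels.index(label)
        return slice(int(self.epoch_marks[i]), int(self.epoch_marks[i + 1]))

    def copy(self) -> "AccelTrace":
        return replace(self, samples=self.samples.copy(), epoch_marks=self.epoch_marks.copy())


@dataclass
class RoiSeries:
    """One trial of source-level virtual-channel time series (ROI x time)."""

    samples: np.ndarray
    fs: float
    roi_labels: tuple[str, ...]
    epoch_marks: np.ndarray
    trial_id: str = ""
    epoch_labels: tuple[str, ...] = EPOCH_ORDER

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.roi_labels = tuple(self.roi_labels)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.roi_labels):
            raise ValueError(
                f"samples must be (n_rois, n_samples) matching {len(self.roi_labels)} labels"
            )
        if len(self.roi_labels) != 10:
            raise ValueError("exactly 10 ROIs are required")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.epoch_labels = tuple(self.epoch_labels)
        self.epoch_marks = _check_epoch_marks(
            self.epoch_marks, self.samples.shape[1], len(self.epoch_labels)
        )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def roi(self, label: str) -> np.ndarray:
        return self.samples[self.roi_labels.index(label)]

    def epoch_slice(self, label: str) -> slice:
        i = self.epoch_labels.index(label)
        return slice(int(self.epoch_marks[i]), int(self.epoch_marks[i + 1]))

    def copy(self) -> "RoiSeries":
        return replace(self, samples=self.samples.copy(), epoch_marks=self.epoch_marks.copy())


@dataclass
class KinematicSummary:
    """Per-trial kinematic scalars.

    ``reaction_time`` is go-cue to reach onset (s); ``mean_velocity`` the mean
    speed over the reach; ``path_length`` the integrated speed; and
    ``hold_variability`` the SD of position over the hold.
    """

    reaction_time: float
    mean_velocity: float
    path_length: float
    hold_variability: float
    outlier_flag: bool = False
    missing: bool = False


@dataclass
class TremorEstimate:
    """Tremor quantification for one epoch of one trial."""

    epoch: str
    peak_freq: float
    amplitude_rms: float
    dominant_axis: np.ndarray

    def __post_init__(self) -> None:
        self.dominant_axis = np.asarray(self.dominant_axis, dtype=np.float64)
        if self.dominant_axis.shape != (3,):
            raise ValueError("dominant_axis must be a 3-vector")


@dataclass
class TFMap:
    """A time-frequency map (time x frequency) with explicit axes.

    ``units`` is one of ``power`` (PSD-scaled), ``percent_change`` (relative to
    a baseline interval, 0 = no change) or ``log_power``.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    units: str = "power"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_times={self.times.size}, n_freqs={self.freqs.size})"
            )
        if self.units not in ("power", "percent_change", "log_power"):
            raise ValueError(f"unknown units {self.units!r}")


@dataclass
class CoherenceResult:
    """Band-averaged magnitude-squared coherence."""

    coherence: float
    band: tuple[float, float]
    n_trials: int
    per_trial: np.ndarray | None = None
    freqs: np.ndarray | None = None
    spectrum: np.ndarray | None = None


@dataclass
class TFTensor:
    """Time x frequency x ROI tensor with epoch concatenation map.

    ``epoch_bounds`` maps epoch label -> (start, stop) on the (possibly
    concatenated) time axis and must partition it exactly. ``normalization``
    tracks the preprocessing state; when ``log_z`` the per-subject mean/SD used
    are retained so trials can be projected into the same space.
    """

    values: np.ndarray
    freqs: np.ndarray
    roi_labels: tuple[str, ...]
    epoch_bounds: dict[str, tuple[int, int]]
    normalization: str = "raw"
    norm_mean: float | None = None
    norm_sd: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.roi_labels = tuple(self.roi_labels)
        if self.values.ndim != 3:
            raise ValueError("values must be time x frequency x ROI")
        n_t, n_f, n_r = self.values.shape
        if n_f != self.freqs.size or n_r != len(self.roi_labels):
            raise ValueError("axis sizes do not match freqs/roi_labels")
        if self.normalization not in ("raw", "log", "log_z"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        bounds = sorted(self.epoch_bounds.values())
        cursor = 0
        for a, b in bounds:
            if a != cursor:
                raise ValueError("epoch_bounds must partition the time axis exactly")
            cursor = b
        if bounds and cursor != n_t:
            raise ValueError("epoch_bounds must cover the full time axis")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def unfold(self) -> np.ndarray:
        """time x (frequency*ROI) matrix, frequency-major column order."""
        n_t = self.values.shape[0]
        return self.values.reshape(n_t, -1)


@dataclass
class ClusterResult:
    """Outcome of a cluster-based permutation test on a 1-D axis."""

    clusters: list[tuple[int, int]]
    masses: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    cluster_forming_p: float
    t_obs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self) -> list[tuple[int, int]]:
        return [c for c, p in zip(self.clusters, self.p_values) if p <= self.alpha]


@dataclass
class OverlapResult:
    """Subject-overlap counts per ROI with binomial tail probabilities."""

    roi_labels: tuple[str, ...]
    counts: np.ndarray
    n_subjects: int
    percentile: float
    p_binom: np.ndarray


def as_epoch_subset(epochs: Sequence[str] | str | None) -> tuple[str, ...]:
    """Normalize an epoch-subset argument against the canonical order."""
    if epochs is None:
        return EPOCH_ORDER
    if isinstance(epochs, str):
        epochs = (epochs,)
    epochs = tuple(epochs)
    unknown = [e for e in epochs if e not in EPOCH_ORDER]
    if unknown:
        raise ValueError(f"unknown epochs {unknown}; valid: {EPOCH_ORDER}")
    return epochs
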