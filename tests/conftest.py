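"""Shared fixtures: small deterministic cohorts and trace builders."""

from __future__ import annotations

import numpy as np
import pytest

from tremornet.config import SynthConfig
from tremornet.datatypes import EPOCH_ORDER, ROI_LABELS, AccelTrace, RoiSeries
from tremornet.synth import generate_cohort


def standard_marks(fs: float = 256.0, cue: float = 2.5) -> np.ndarray:
    durs = {"rest": 3.0, "posture": 3.0, "cue": cue, "reach": 2.0, "hold": 1.5}
    samples = [int(round(durs[e] * fs)) for e in EPOCH_ORDER]
    return np.concatenate([[0], np.cumsum(samples)])


@pytest.fixture(scope="session")
def fs() -> float:
    return 256.0


@pytest.fixture()
def zero_trace(fs) -> AccelTrace:
    marks = standard_marks(fs)
    return AccelTrace(samples=np.zeros((int(marks[-1]), 3)), fs=fs, epoch_marks=marks)


@pytest.fixture()
def noise_series(fs) -> RoiSeries:
    marks = standard_marks(fs)
    rng = np.random.default_rng(0)
    return RoiSeries(
        samples=rng.standard_normal((10, int(marks[-1]))),
        fs=fs,
        roi_labels=ROI_LABELS,
        epoch_marks=marks,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2 controls + 2 patients x 8 trials; shared across read-only tests."""
    cfg = SynthConfig(n_control=2, n_et=2, n_trials_per_subject=8, seed=42)
    return generate_cohort(cfg)
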