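"""Movement-onset detection and per-trial kinematic summaries.

Onsets come from thresholding the Z-normalized rectified accelerometer sum
(Z statistics defined on the rest epoch); summaries operate on 1-D speed and
position profiles. Outlier screening uses a |Z| > 1.96 rule within each group
of values, and condition effects are tested with an ANOVA on subject-demeaned
condition means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import EPOCH_ORDER, AccelTrace, KinematicSummary

logger = logging.getLogger(__name__)

#: Minimum continuous threshold-crossing duration (s) accepted as an onset.
DEBOUNCE_S = 0.025


def posture_onset(
    trace: AccelTrace, z_threshold: float = 3.0, debounce: float = DEBOUNCE_S
) -> int | None:
    """First sample where the rectified triaxial sum exceeds ``z_threshold``.

    The Z reference (mean/SD) is computed from the rest epoch. The crossing
    must be sustained for ``debounce`` seconds to count, which suppresses
    single-sample noise excursions. Returns None when no onset is found.
    """
    rest = trace.epoch_slice("rest")
    summed = np.abs(trace.samples).sum(axis=1)
    ref = summed[rest]
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        logger.warning("posture_onset: constant rest segment in %s", trace.trial_id)
        return None
    if z_threshold <= 0:
        # degenerate threshold: detection is immediate
        return 0
    z = (summed - mu) / sd
    above = z > z_threshold
    need = max(1, int(round(debounce * trace.fs)))
    # first index where `above` holds for `need` consecutive samples
    if need == 1:
        hits = np.flatnonzero(above)
        return int(hits[0]) if hits.size else None
    run = np.convolve(above.astype(int), np.ones(need, dtype=int), mode="valid")
    hits = np.flatnonzero(run == need)
    if hits.size == 0:
        logger.info("posture_onset: no sustained crossing in %s", trace.trial_id)
        return None
    return int(hits[0])


def trial_summaries(
    speed: np.ndarray,
    position: np.ndarray,
    epoch_marks: np.ndarray,
    fs: float,
    epoch_labels: tuple[str, ...] = EPOCH_ORDER,
    onset_speed_fraction: float = 0.05,
) -> KinematicSummary:
    """Kinematic scalars for one trial from 1-D speed/position profiles.

    Reach onset is the first sample in the reach epoch where speed exceeds
    ``onset_speed_fraction`` of the reach peak; reaction time is measured
    from the go cue (reach-epoch start). Mean velocity and path length are
    computed over the movement (onset to reach-epoch end), hold variability
    as the SD of position over the hold epoch.
    """
    speed = np.asarray(speed, dtype=np.float64)
    position = np.asarray(position, dtype=np.float64)
    i_reach = epoch_labels.index("reach")
    go = int(epoch_marks[i_reach])
    reach_end = int(epoch_marks[i_reach + 1])
    hold = slice(reach_end, int(epoch_marks[i_reach + 2]) if i_reach + 2 < len(epoch_marks) else None)

    segment = speed[go:reach_end]
    if segment.size < 3:
        return KinematicSummary(np.nan, np.nan, np.nan, np.nan, missing=True)
    peak = segment.max()
    moving = np.flatnonzero(segment > onset_speed_fraction * peak) if peak > 0 else np.array([])
    if moving.size < 3:
        return KinematicSummary(np.nan, np.nan, np.nan, np.nan, missing=True)
    onset = go + int(moving[0])
    move = speed[onset:reach_end]
    reaction_time = (onset - go) / fs
    mean_velocity = float(move.mean())
    path_length = float(move.sum() / fs)
    hold_pos = position[hold]
    hold_variability = float(hold_pos.std()) if hold_pos.size else np.nan
    return KinematicSummary(reaction_time, mean_velocity, path_length, hold_variability)


def zscore_outlier_filter(values: np.ndarray, limit: float = 1.96) -> np.ndarray:
    """Boolean retain-mask: False where |Z| > limit against the supplied group.

    Each value's Z is computed against the mean/SD of the *other* values
    (leave-one-out), so a gross outlier cannot mask itself by inflating the
    spread: with an inclusive SD the largest attainable |Z| in a group of n
    is (n-1)/sqrt(n), below 1.96 for n <= 4. Zero remaining variance retains
    the value when it equals the rest and removes it otherwise.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values to screen outliers")
    if values.std() == 0:
        return np.ones(n, dtype=bool)
    keep = np.ones(n, dtype=bool)
    total = values.sum()
    for i in range(n):
        rest_mean = (total - values[i]) / (n - 1)
        rest = np.delete(values, i)
        sd = rest.std()
        if sd == 0:
            keep[i] = values[i] == rest_mean
        else:
            keep[i] = abs(values[i] - rest_mean) / sd <= limit
    return keep


def augment_trial_table(
    trials: pd.DataFrame,
    columns: tuple[str, ...] = ("reaction_time", "mean_velocity", "path_length",
                                "hold_variability"),
    limit: float = 1.96,
) -> pd.DataFrame:
    """Add per-column outlier flags screened within each subject's trials.

    Returns a copy of the trial table with one boolean ``<col>_outlier``
    column per kinematic; subjects with fewer than 3 trials are never
    flagged. (The across-subject screen on condition means lives in
    :func:`condition_anova`.)
    """
    out = trials.copy()
    group_cols = ["subject_id"]
    for col in columns:
        flags = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby(group_cols, observed=True).groups.items():
            values = out.loc[idx, col].to_numpy(dtype=float)
            if values.size >= 3:
                flags[out.index.get_indexer(idx)] = ~zscore_outlier_filter(values, limit)
        out[f"{col}_outlier"] = flags
    return out


def condition_anova(
    trials: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("uncertainty", "target_size"),
    outlier_limit: float | None = 1.96,
) -> pd.DataFrame:
    """ANOVA on subject-demeaned condition means.

    Trials are first averaged per subject x condition cell, the subject mean
    is subtracted (so only within-subject condition variance is tested), and
    an OLS ANOVA over the named factors is fitted. Optionally removes
    |Z| > ``outlier_limit`` cell means first. Returns the ANOVA table with
    F statistics and p-values per factor.
    """
    for f in factors:
        if trials[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    cells = (
        trials.groupby(["subject_id", *factors], observed=True)[response]
        .mean()
        .reset_index()
    )
    if outlier_limit is not None and len(cells) >= 3:
        keep = zscore_outlier_filter(cells[response].to_numpy(), limit=outlier_limit)
        cells = cells.loc[keep]
    demeaned = cells.copy()
    demeaned[response] = cells[response] - cells.groupby("subject_id")[response].transform("mean")
    formula = f"{response} ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=demeaned).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return table.rename(columns={"PR(>F)": "p"})
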