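"""Group and trial-level inference: cluster permutation tests, overlap
binomial statistics, BH-FDR and Cook's-screened correlation.

Cluster tests operate on 1-D time courses (latent dynamics or band power):
pointwise two-sided t statistics are thresholded at the cluster-forming
level, contiguous suprathreshold runs are scored by their summed t (mass),
and the maximum |mass| over group-label permutations (or sign flips for
paired data) provides the family-wise null. Permutation p-values use the
plus-one rule and are never exactly zero.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .datatypes import ClusterResult, OverlapResult


def binomial_overlap_p(k: int, n: int, p: float = 0.15) -> float:
    """Exact binomial tail P(X >= k) with X ~ Binomial(n, p).

    The overlap statistic: probability that k or more of n subjects exceed
    their own percentile threshold at one location by chance.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0 < p < 1:
        raise ValueError(f"p={p} outside (0, 1)")
    return float(sst.binom.sf(k - 1, n, p))


def overlap_map(
    subject_maps: np.ndarray, roi_labels: tuple[str, ...], percentile: float = 85.0
) -> OverlapResult:
    """Count subjects whose own-percentile threshold is exceeded per ROI.

    ``subject_maps`` is (n_subjects, n_rois); each subject is thresholded at
    their own ``percentile`` across ROIs, counts are tested against
    Binomial(N, 1 - percentile/100).
    """
    subject_maps = np.asarray(subject_maps, dtype=np.float64)
    if subject_maps.ndim != 2 or subject_maps.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_rois) subject maps")
    n_subj, n_roi = subject_maps.shape
    if n_roi != len(roi_labels):
        raise ValueError("roi_labels length does not match maps")
    counts = np.zeros(n_roi, dtype=int)
    for s in range(n_subj):
        row = subject_maps[s]
        if np.allclose(row, row[0]):
            continue  # constant map: no suprathreshold entries
        thr = np.percentile(row, percentile)
        counts += row > thr
    p_tail = 1.0 - percentile / 100.0
    p_binom = np.array([binomial_overlap_p(int(k), n_subj, p_tail) for k in counts])
    return OverlapResult(
        roi_labels=tuple(roi_labels),
        counts=counts,
        n_subjects=n_subj,
        percentile=percentile,
        p_binom=p_binom,
    )


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Welch t and df for (n_a, T) vs (n_b, T); vectorized over perms."""
    na, nb = a.shape[-2], b.shape[-2]
    ma, mb = a.mean(axis=-2), b.mean(axis=-2)
    va = a.var(axis=-2, ddof=1) / na
    vb = b.var(axis=-2, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, df


def _clusters_from_t(t: np.ndarray, crit: np.ndarray) -> list[tuple[int, int, float]]:
    """Contiguous |t| > crit runs as (start, stop, mass); signs kept separate."""
    out = []
    above = np.abs(t) > crit
    sign = np.sign(t)
    i = 0
    n = t.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j] and sign[j] == sign[i]:
                j += 1
            out.append((i, j, float(t[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def cluster_permutation(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    cluster_p: float = 0.1,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster-based permutation test between two subject x time arrays.

    ``cluster_p`` is only the cluster-forming threshold (two-sided pointwise
    level that lets a cluster enter permutation testing), not the alpha for
    cluster significance, which is ``alpha``. Unpaired contrasts use Welch t
    (group sizes are typically unequal) with group-label exchange; paired
    contrasts use a one-sample t on differences with sign flipping.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("time axes differ between groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test needs equal subject counts")
        if a.shape[0] < 3:
            raise ValueError("need >= 3 pairs")
        d = a - b
        n = d.shape[0]
        sd = d.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise ValueError("zero variance at all time points")
        with np.errstate(invalid="ignore", divide="ignore"):
            t_obs = d.mean(axis=0) / (sd / np.sqrt(n))
        t_obs = np.nan_to_num(t_obs)
        crit = np.full(d.shape[1], sst.t.ppf(1 - cluster_p / 2, n - 1))
        clusters = _clusters_from_t(t_obs, crit)
        # sign-flip null, vectorized over permutations
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n, 1))
        flipped = flips * d[None, :, :]
        mean = flipped.mean(axis=1)
        std = flipped.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_null = mean / (std / np.sqrt(n))
        t_null = np.nan_to_num(t_null)
        null_max = _max_cluster_mass(t_null, crit)
    else:
        if a.shape[0] < 3 or b.shape[0] < 3:
            raise ValueError("need >= 3 subjects per group")
        t_obs, df = _welch_t(a, b)
        if not np.any(np.isfinite(t_obs)):
            raise ValueError("zero variance at all time points")
        t_obs = np.nan_to_num(t_obs)
        df = np.nan_to_num(df, nan=a.shape[0] + b.shape[0] - 2.0)
        crit = sst.t.ppf(1 - cluster_p / 2, np.maximum(df, 1.0))
        clusters = _clusters_from_t(t_obs, crit)
        pooled = np.vstack([a, b])
        n_tot, na = pooled.shape[0], a.shape[0]
        perm_idx = np.stack([rng.permutation(n_tot) for _ in range(n_perm)])
        permuted = pooled[perm_idx]  # (n_perm, n_tot, T)
        t_null, _ = _welch_t(permuted[:, :na, :], permuted[:, na:, :])
        t_null = np.nan_to_num(t_null)
        null_max = _max_cluster_mass(t_null, crit)

    masses = np.array([m for *_ignored, m in clusters])
    p_vals = np.array(
        [(1 + np.sum(null_max >= abs(m))) / (1 + n_perm) for m in masses]
    )
    return ClusterResult(
        clusters=[(i, j) for i, j, _ in clusters],
        masses=masses,
        p_values=p_vals,
        n_permutations=n_perm,
        alpha=alpha,
        cluster_forming_p=cluster_p,
        t_obs=t_obs,
    )


def _max_cluster_mass(t_null: np.ndarray, crit: np.ndarray) -> np.ndarray:
    """Maximum |cluster mass| per permutation (rows of t_null)."""
    out = np.zeros(t_null.shape[0])
    for r in range(t_null.shape[0]):
        cl = _clusters_from_t(t_null[r], crit)
        out[r] = max((abs(m) for *_ignored, m in cl), default=0.0)
    return out


def quartile_split_test(
    trial_latents: dict[str, np.ndarray],
    trial_values: dict[str, np.ndarray],
    cluster_p: float = 0.1,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Paired cluster test of bottom- vs top-quartile trial averages.

    For each subject (dict key) with (n_trials, T) latents and matching
    per-trial values, trials with value <= Q1 form the low split and
    value >= Q3 the high split (inclusive bounds keep quartiles non-empty at
    small n; ties resolve by the stable trial order through the inclusive
    threshold). Subject averages are then compared with a paired cluster
    permutation test.
    """
    lows, highs = [], []
    for subject, latents in trial_latents.items():
        values = np.asarray(trial_values[subject], dtype=np.float64)
        latents = np.asarray(latents, dtype=np.float64)
        if latents.shape[0] != values.size:
            raise ValueError(f"subject {subject}: trial counts differ")
        if values.size < 8:
            raise ValueError(f"subject {subject}: need >= 8 trials for a quartile split")
        q1, q3 = np.percentile(values, [25, 75])
        lows.append(latents[values <= q1].mean(axis=0))
        highs.append(latents[values >= q3].mean(axis=0))
    return cluster_permutation(
        np.vstack(highs), np.vstack(lows), paired=True,
        cluster_p=cluster_p, alpha=alpha, n_perm=n_perm, seed=seed,
    )


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected mask, monotone adjusted p)."""
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return rejected, adjusted


def cooks_screened_correlation(
    x: np.ndarray, y: np.ndarray, multiplier: float = 3.0
) -> dict:
    """Pearson correlation after one round of Cook's-distance screening.

    Fits OLS y ~ x, removes points whose Cook's distance exceeds
    ``multiplier`` times the mean distance, refits once, and reports Pearson
    r, R^2 and p on the retained points. Fewer than 4 retained points flags
    the estimate unreliable.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched x/y with at least 4 points")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    if fit.ssr <= 1e-12 * max(np.var(y) * y.size, 1e-30):
        # perfect fit: distances are ratios of rounding noise, nothing to screen
        keep = np.ones(x.size, dtype=bool)
    else:
        cooks = np.nan_to_num(fit.get_influence().cooks_distance[0], nan=0.0, posinf=0.0)
        keep = np.ones(x.size, dtype=bool) if cooks.mean() == 0 else (
            cooks <= multiplier * cooks.mean()
        )
    removed = np.flatnonzero(~keep)
    xr, yr = x[keep], y[keep]
    unreliable = xr.size < 4
    if unreliable:
        xr, yr = x, y
        removed = np.array([], dtype=int)
    r, p = sst.pearsonr(xr, yr)
    return {
        "r": float(r),
        "r2": float(r**2),
        "p": float(p),
        "removed": removed,
        "unreliable": bool(unreliable),
    }
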