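"""Time-frequency principal component analysis (tfPCA).

Decomposes epoch-concatenated time x frequency x ROI power into a small set
of spatial-spectral components (unit-norm loadings over frequency x ROI)
with latent temporal dynamics (component x time). The fit is a plain SVD of
the column-centered unfolded matrix, applied to group-averaged data; single
trials are then back-projected through the group loadings and column means
so trial latents live in the fitted space.

Preprocessing: power is log-scaled (floored at a small epsilon) and
Z-normalized per subject with pooled mean/SD over all entries; the statistics
are retained on the tensor so trials from the same subject can be projected
consistently and the transform inverted exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import TFMap, TFTensor

logger = logging.getLogger(__name__)


@dataclass
class TfpcaModel:
    """Group-level tfPCA fit.

    ``coefficients`` is (n_components, n_freqs*n_rois) with orthonormal rows,
    frequency-major column order matching :meth:`TFTensor.unfold`;
    ``latent`` is (n_components, n_times) over the fitted (concatenated)
    time axis; ``explained_variance`` the per-component variance fractions in
    descending order.
    """

    coefficients: np.ndarray
    latent: np.ndarray
    explained_variance: np.ndarray
    column_means: np.ndarray
    freqs: np.ndarray
    roi_labels: tuple[str, ...]
    epoch_bounds: dict[str, tuple[int, int]]
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[0]

    def component_map(self, k: int) -> np.ndarray:
        """Loadings of component ``k`` reshaped to (frequency, ROI)."""
        return self.coefficients[k].reshape(self.freqs.size, len(self.roi_labels))


def build_tensor(
    maps: dict[str, dict[str, TFMap]],
    roi_labels: tuple[str, ...],
    epoch_order: tuple[str, ...],
    log_floor: float | None = None,
    normalize: bool = True,
) -> TFTensor:
    """Assemble per-ROI, per-epoch TF maps into one subject tensor.

    ``maps[roi][epoch]`` must share a frequency axis; epochs are concatenated
    along time in task order. Power is log-transformed (nonpositive entries
    floored at ``log_floor``, default = smallest positive value x 1e-3, and
    counted) and, when ``normalize``, Z-scored with the subject's pooled
    mean/SD over all finite entries.
    """
    freqs = None
    blocks = []
    bounds: dict[str, tuple[int, int]] = {}
    cursor = 0
    for epoch in epoch_order:
        per_roi = []
        for roi in roi_labels:
            tfm = maps[roi][epoch]
            if freqs is None:
                freqs = tfm.freqs
            elif not np.array_equal(freqs, tfm.freqs):
                raise ValueError("all maps must share one frequency axis")
            per_roi.append(tfm.values)
        block = np.stack(per_roi, axis=-1)  # time x freq x roi
        blocks.append(block)
        bounds[epoch] = (cursor, cursor + block.shape[0])
        cursor += block.shape[0]
    values = np.concatenate(blocks, axis=0)

    finite = values[np.isfinite(values)]
    positive = finite[finite > 0]
    if positive.size == 0:
        raise ValueError("tensor contains no positive power values")
    floor = log_floor if log_floor is not None else positive.min() * 1e-3
    n_floored = int(np.sum(np.isfinite(values) & (values <= 0)))
    if n_floored:
        logger.warning("build_tensor: %d nonpositive entries floored at %.3g", n_floored, floor)
    logged = np.log(np.maximum(values, floor))

    if not normalize:
        return TFTensor(values=logged, freqs=freqs, roi_labels=roi_labels,
                        epoch_bounds=bounds, normalization="log")
    finite_logged = logged[np.isfinite(logged)]
    mean = float(finite_logged.mean())
    sd = float(max(finite_logged.std(), 1e-12))
    normed = (logged - mean) / sd
    return TFTensor(values=normed, freqs=freqs, roi_labels=roi_labels, epoch_bounds=bounds,
                    normalization="log_z", norm_mean=mean, norm_sd=sd)


def unnormalize(tensor: TFTensor) -> np.ndarray:
    """Invert the per-subject Z step, recovering log power exactly."""
    if tensor.normalization != "log_z":
        raise ValueError("tensor is not Z-normalized")
    return tensor.values * tensor.norm_sd + tensor.norm_mean


def fit(tensor: TFTensor, n_components: int = 4) -> TfpcaModel:
    """Fit tfPCA to a (group-mean) tensor by SVD of the unfolded matrix.

    Component signs are fixed so each row's largest-magnitude coefficient is
    positive. NaN entries (e.g. edge windows) are replaced by the column mean
    before centering, i.e. they contribute nothing to the covariance.
    """
    if tensor.normalization != "log_z":
        raise ValueError("fit expects a log-scaled, Z-normalized tensor")
    x = tensor.unfold().copy()
    n_t, n_v = x.shape
    if n_components > min(n_t, n_v):
        raise ValueError(f"n_components {n_components} exceeds min(time, freq*roi)")
    col_mean = np.nanmean(x, axis=0)
    nan_mask = ~np.isfinite(x)
    if nan_mask.any():
        x[nan_mask] = np.broadcast_to(col_mean, x.shape)[nan_mask]
    centered = x - col_mean
    total_var = float(np.sum(centered**2))
    if total_var == 0:
        raise ValueError("degenerate tensor: zero variance after centering")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    coeffs = vt[:n_components]
    signs = np.sign(coeffs[np.arange(n_components), np.argmax(np.abs(coeffs), axis=1)])
    coeffs = coeffs * signs[:, None]
    latent = centered @ coeffs.T  # (time, k)
    explained = (s[:n_components] ** 2) / total_var
    return TfpcaModel(
        coefficients=coeffs,
        latent=latent.T,
        explained_variance=explained,
        column_means=col_mean,
        freqs=tensor.freqs,
        roi_labels=tensor.roi_labels,
        epoch_bounds=dict(tensor.epoch_bounds),
        total_variance=total_var,
    )


def backproject(model: TfpcaModel, tensor: TFTensor) -> np.ndarray:
    """Project a (trial) tensor onto the group components.

    The tensor must be normalized with the same subject statistics and share
    the fit's frequency/ROI axes. Centering uses the group-fit column means so
    trial latents are comparable across trials and subjects. Returns
    (n_components, n_times).
    """
    if not np.array_equal(model.freqs, tensor.freqs) or model.roi_labels != tensor.roi_labels:
        diff = {
            "freqs_model": model.freqs.shape,
            "freqs_tensor": tensor.freqs.shape,
            "rois_model": model.roi_labels,
            "rois_tensor": tensor.roi_labels,
        }
        raise ValueError(f"axis mismatch between model and tensor: {diff}")
    x = tensor.unfold().copy()
    nan_mask = ~np.isfinite(x)
    if nan_mask.any():
        x[nan_mask] = np.broadcast_to(model.column_means, x.shape)[nan_mask]
    centered = x - model.column_means
    return (centered @ model.coefficients.T).T


def reconstruct(model: TfpcaModel, k: int | None = None) -> tuple[np.ndarray, float]:
    """Rank-k reconstruction of the fitted data and its relative squared error.

    With k components the error equals 1 - sum of the first k explained
    variance fractions (an algebraic identity of the SVD).
    """
    if k is None:
        k = model.n_components
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds fitted components ({model.n_components})")
    approx = model.latent[:k].T @ model.coefficients[:k] + model.column_means
    if k == 0:
        approx = np.broadcast_to(model.column_means, (model.latent.shape[1],
                                                      model.column_means.size)).copy()
    fitted = model.latent.T @ model.coefficients + model.column_means
    # residual relative to the centered fitted data's total variance
    err = 1.0 - float(model.explained_variance[:k].sum())
    return approx, err


def match_components(model: TfpcaModel, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one match of fitted components to reference patterns.

    ``patterns`` is (n_patterns, n_freqs*n_rois). Returns (assignment,
    |correlation|) where assignment[i] is the component index matched to
    pattern i. Used for parameter-recovery checks.
    """
    n_p = patterns.shape[0]
    corr = np.zeros((n_p, model.n_components))
    for i in range(n_p):
        for j in range(model.n_components):
            c = np.corrcoef(patterns[i], model.coefficients[j])[0, 1]
            corr[i, j] = np.abs(c)
    assignment = np.full(n_p, -1)
    taken: set[int] = set()
    for _ in range(n_p):
        masked = corr.copy()
        masked[assignment >= 0] = -1
        for j in taken:
            masked[:, j] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        assignment[i] = j
        taken.add(int(j))
    scores = corr[np.arange(n_p), assignment]
    return assignment, scores
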