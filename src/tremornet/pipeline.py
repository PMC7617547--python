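"""End-to-end orchestration: simulate -> quantify -> decompose -> test.

Each stage reads/writes fixed on-disk artifacts (HDF5 cohorts and models,
CSV tables, a JSON/text report) so a run is reproducible from its config
and seed. The single run seed is expanded into independent module streams:
the generator consumes ``SynthConfig.seed`` (overridden by the run seed when
one is given) and the permutation tests a stream derived as
``SeedSequence([seed, 7919])``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral, stats, tfpca
from .config import RunConfig
from .datatypes import EPOCH_ORDER, ROI_LABELS, TFTensor
from .io import file_sha256, read_cohort, save_model, write_cohort
from .synth import Cohort, generate_cohort
from .tremor import cohort_tremor_table

logger = logging.getLogger(__name__)

#: Frames per epoch on the concatenated TF axis use these fixed windows (s),
#: locked to each epoch's onset; the cue window is the minimum cue duration
#: so all trials contribute the same number of frames despite cue jitter.
EPOCH_TF_WINDOWS: dict[str, float] = {
    "rest": 3.0, "posture": 3.0, "cue": 1.5, "reach": 2.0, "hold": 1.5,
}


def _stats_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 7919]))


def trial_tf_maps(series, freqs: np.ndarray) -> dict[str, dict[str, spectral.TFMap]]:
    """Per-ROI, per-epoch TF maps of one trial on the fixed epoch windows."""
    hop_n = max(1, int(round(spectral.HOP_S * series.fs)))
    all_values, _ = spectral.tf_transform_multi(series.samples, series.fs, freqs)
    maps: dict[str, dict[str, spectral.TFMap]] = {}
    for r_idx, roi in enumerate(series.roi_labels):
        per_epoch = {}
        for epoch in EPOCH_ORDER:
            sl = series.epoch_slice(epoch)
            start_frame = sl.start // hop_n
            n_frames = int(round(EPOCH_TF_WINDOWS[epoch] * series.fs / hop_n))
            block = all_values[r_idx, start_frame : start_frame + n_frames]
            times = (np.arange(block.shape[0]) * hop_n) / series.fs
            per_epoch[epoch] = spectral.TFMap(values=block, times=times, freqs=freqs)
        maps[roi] = per_epoch
    return maps


def _mean_maps(trial_maps: list[dict]) -> dict:
    """Average power maps over trials (per ROI, per epoch).

    Grid cells that are NaN in every trial (edge windows) stay NaN.
    """
    import warnings

    out = {}
    for roi in trial_maps[0]:
        out[roi] = {}
        for epoch in trial_maps[0][roi]:
            stack = np.stack([m[roi][epoch].values for m in trial_maps])
            ref = trial_maps[0][roi][epoch]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(stack, axis=0)
            out[roi][epoch] = spectral.TFMap(values=mean, times=ref.times, freqs=ref.freqs)
    return out


def subject_tensors(
    cohort: Cohort, subject_id: str, freqs: np.ndarray
) -> tuple[TFTensor, list[TFTensor]]:
    """Subject-mean log-Z tensor plus per-trial tensors in the same space."""
    trial_ids = cohort.subject_trials(subject_id)
    trial_maps = [trial_tf_maps(cohort.roi[(subject_id, t)], freqs) for t in trial_ids]
    subj_tensor = tfpca.build_tensor(_mean_maps(trial_maps), ROI_LABELS, EPOCH_ORDER)
    m, s = subj_tensor.norm_mean, subj_tensor.norm_sd
    trial_tensors = []
    for maps in trial_maps:
        raw = tfpca.build_tensor(maps, ROI_LABELS, EPOCH_ORDER, normalize=False)
        values = (raw.values - m) / s
        trial_tensors.append(
            TFTensor(values=values, freqs=raw.freqs, roi_labels=raw.roi_labels,
                     epoch_bounds=raw.epoch_bounds, normalization="log_z",
                     norm_mean=m, norm_sd=s)
        )
    return subj_tensor, trial_tensors


def run_simulate(config: RunConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Generate a cohort and write it plus a manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5_path, csv_path = out / "cohort.h5", out / "trials.csv"
    if (h5_path.exists() or csv_path.exists()) and not force:
        raise FileExistsError(f"outputs exist in {out}; pass force=True/--force to overwrite")
    cohort = generate_cohort(config.synth)
    write_cohort(cohort, h5_path, csv_path)
    config.to_yaml(out / "config.yaml")
    manifest = {
        "seed": config.synth.seed,
        "config_sha256": file_sha256(out / "config.yaml"),
        "cohort_sha256": file_sha256(h5_path),
        "trials_sha256": file_sha256(csv_path),
        "n_trials": int(len(cohort.trials)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_analyze(config: RunConfig, cohort_dir: str | Path, out_dir: str | Path) -> dict:
    """Run the full analysis chain on a cohort directory.

    Produces: tremor estimates CSV, tfPCA model HDF5, subject latents, group
    ERD contrasts per band/ROI, latent cluster statistics per component and
    epoch (BH-FDR corrected), quartile-split tests against mean velocity, and
    a tremor-band coherence overlap map over patients.
    """
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_dir / "cohort.h5", cohort_dir / "trials.csv")
    rng = _stats_rng(config.seed)
    freqs = np.arange(config.tf_fmin, config.tf_fmax + 1e-9, config.tf_fstep)

    stage = "tremor"
    try:
        tremor_table = cohort_tremor_table(cohort)
        tremor_table.to_csv(out / "tremor.csv", index=False)
        from .kinematics import augment_trial_table

        augment_trial_table(cohort.trials).to_csv(out / "trials_augmented.csv", index=False)

        stage = "time-frequency"
        subjects = cohort.subjects
        subj_t: dict[str, TFTensor] = {}
        trial_t: dict[str, list[TFTensor]] = {}
        for sid in subjects:
            subj_t[sid], trial_t[sid] = subject_tensors(cohort, sid, freqs)

        stage = "tfpca"
        group_values = np.mean([subj_t[s].values for s in subjects], axis=0)
        ref = subj_t[subjects[0]]
        group_tensor = TFTensor(values=group_values, freqs=ref.freqs,
                                roi_labels=ref.roi_labels, epoch_bounds=ref.epoch_bounds,
                                normalization="log_z", norm_mean=0.0, norm_sd=1.0)
        model = tfpca.fit(group_tensor, n_components=config.n_components)
        save_model(model, out / "tfpca_model.h5")
        subj_latents = {s: tfpca.backproject(model, subj_t[s]) for s in subjects}

        stage = "group-contrasts"
        erd_rows = []
        reach = ref.epoch_bounds["reach"]
        rest = ref.epoch_bounds["rest"]
        f_idx = {band: (freqs >= lo) & (freqs <= hi) for band, (lo, hi) in config.bands.items()}
        groups = {s: cohort.group_of(s) for s in subjects}
        for band, sel in f_idx.items():
            for r_i, roi in enumerate(ROI_LABELS):
                per_subject = {}
                for s in subjects:
                    v = subj_t[s].values  # log_z
                    base = np.nanmean(v[rest[0]:rest[1], sel, r_i])
                    move = np.nanmean(v[reach[0]:reach[1], sel, r_i])
                    per_subject[s] = move - base  # log-power change vs rest
                a = [per_subject[s] for s in subjects if groups[s] == "ET"]
                b = [per_subject[s] for s in subjects if groups[s] == "control"]
                from scipy import stats as sst
                t, p = sst.ttest_ind(a, b, equal_var=False)
                erd_rows.append({"band": band, "roi": roi, "mean_et": np.mean(a),
                                 "mean_control": np.mean(b), "t": t, "p": p})
        pd.DataFrame(erd_rows).to_csv(out / "erd_contrasts.csv", index=False)

        stage = "latent-statistics"
        et = [s for s in subjects if groups[s] == "ET"]
        ctl = [s for s in subjects if groups[s] == "control"]
        cluster_rows = []
        for comp in range(model.n_components):
            for epoch in ("posture", "cue", "reach", "hold"):
                a0, b0 = ref.epoch_bounds[epoch]
                ga = np.vstack([subj_latents[s][comp, a0:b0] for s in et])
                gb = np.vstack([subj_latents[s][comp, a0:b0] for s in ctl])
                res = stats.cluster_permutation(
                    ga, gb, cluster_p=config.cluster_forming_p, alpha=config.alpha,
                    n_perm=config.n_permutations, seed=rng,
                )
                p_min = float(res.p_values.min()) if res.p_values.size else 1.0
                best = res.clusters[int(np.argmin(res.p_values))] if res.p_values.size else None
                cluster_rows.append({
                    "component": comp + 1, "epoch": epoch, "p": p_min,
                    "cluster": str(best),
                    "mass": float(res.masses[int(np.argmin(res.p_values))]) if best else 0.0,
                })
        cluster_df = pd.DataFrame(cluster_rows)
        rejected, adjusted = stats.bh_fdr(cluster_df["p"].to_numpy(), q=config.alpha)
        cluster_df["p_fdr"] = adjusted
        cluster_df["significant_fdr"] = rejected
        cluster_df.to_csv(out / "latent_group_clusters.csv", index=False)

        stage = "quartile-splits"
        quartile_rows = []
        trials = cohort.trials
        for comp in range(model.n_components):
            for epoch in ("reach", "hold"):
                a0, b0 = ref.epoch_bounds[epoch]
                latents, values = {}, {}
                for s in subjects:
                    tl = np.stack([tfpca.backproject(model, tt)[comp, a0:b0]
                                   for tt in trial_t[s]])
                    vals = trials.loc[trials.subject_id == s].sort_values("trial_id")[
                        "mean_velocity"].to_numpy()
                    if vals.size >= 8:
                        latents[s], values[s] = tl, vals
                if len(latents) < 3:
                    continue
                res = stats.quartile_split_test(
                    latents, values, cluster_p=config.cluster_forming_p,
                    alpha=config.alpha, n_perm=config.n_permutations, seed=rng,
                )
                p_min = float(res.p_values.min()) if res.p_values.size else 1.0
                quartile_rows.append({"component": comp + 1, "epoch": epoch,
                                      "kinematic": "mean_velocity", "p": p_min})
        qdf = pd.DataFrame(quartile_rows)
        if len(qdf):
            _, q_adj = stats.bh_fdr(qdf["p"].to_numpy(), q=config.alpha)
            qdf["p_fdr"] = q_adj
        qdf.to_csv(out / "quartile_splits.csv", index=False)

        stage = "coherence-overlap"
        subject_maps = []
        for s in et:
            trial_ids = cohort.subject_trials(s)
            roi_trials = [cohort.roi[(s, t)] for t in trial_ids]
            refs = [cohort.tremor_reference[(s, t)] for t in trial_ids]
            row = []
            for roi in ROI_LABELS:
                sigs = [tr.roi(roi) for tr in roi_trials]
                row.append(spectral.band_coherence(
                    sigs, refs, roi_trials[0].fs, band=config.bands["tremor"]).coherence)
            subject_maps.append(row)
        if len(subject_maps) >= 2:
            overlap = stats.overlap_map(np.asarray(subject_maps), ROI_LABELS,
                                        percentile=config.overlap_percentile)
            pd.DataFrame({
                "roi": overlap.roi_labels, "count": overlap.counts,
                "n_subjects": overlap.n_subjects, "p_binom": overlap.p_binom,
            }).to_csv(out / "overlap_map.csv", index=False)
    except Exception:
        logger.exception("analysis failed at stage %r; partial outputs preserved in %s",
                         stage, out)
        raise

    summary = {
        "n_subjects": len(subjects),
        "explained_variance": [float(v) for v in model.explained_variance],
        "n_fdr_significant_group_clusters": int(cluster_df["significant_fdr"].sum()),
    }
    (out / "analysis_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_report(results_dir: str | Path) -> dict:
    """Collect stage outputs into one machine-readable summary + text."""
    results = Path(results_dir)
    report: dict = {"sections": {}}
    expected = {
        "tremor": "tremor.csv",
        "erd_contrasts": "erd_contrasts.csv",
        "latent_group_clusters": "latent_group_clusters.csv",
        "quartile_splits": "quartile_splits.csv",
        "overlap_map": "overlap_map.csv",
    }
    lines = ["tremornet analysis report", "=" * 30]
    for name, fname in expected.items():
        path = results / fname
        if not path.exists():
            report["sections"][name] = {"status": "missing", "file": fname}
            lines.append(f"[{name}] MISSING ({fname})")
            continue
        df = pd.read_csv(path)
        section = {"status": "empty" if df.empty else "ok", "rows": int(len(df))}
        if name == "latent_group_clusters" and not df.empty:
            sig = df[df.get("significant_fdr", False) == True]  # noqa: E712
            section["fdr_significant"] = sig[["component", "epoch", "p"]].to_dict("records")
        report["sections"][name] = section
        lines.append(f"[{name}] {section['status']} ({section['rows']} rows)")
    summary_path = results / "analysis_summary.json"
    if summary_path.exists():
        report["summary"] = json.loads(summary_path.read_text())
    (results / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (results / "report.txt").write_text("\n".join(lines) + "\n")
    return report
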