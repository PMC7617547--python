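"""On-disk formats: HDF5 cohorts and models, CSV tables, YAML configs.

Cohort layout: ``/subjects/<id>/trials/<k>/{accel, roi, reference}`` with
``fs``, ``epoch_marks``, ``epoch_labels`` and ``roi_labels`` attributes; the
trial table is a CSV with the fixed column order of
:data:`tremornet.synth.TRIAL_COLUMNS`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SynthConfig
from .datatypes import AccelTrace, RoiSeries
from .synth import TRIAL_COLUMNS, Cohort
from .tfpca import TfpcaModel


def write_cohort(cohort: Cohort, h5_path: str | Path, csv_path: str | Path) -> None:
    h5_path, csv_path = Path(h5_path), Path(csv_path)
    with h5py.File(h5_path, "w") as f:
        if cohort.config is not None:
            f.attrs["config_json"] = json.dumps(cohort.config.to_dict(), sort_keys=True)
        subjects = f.create_group("subjects")
        for (subject_id, trial_id), trace in cohort.accel.items():
            g = subjects.require_group(f"{subject_id}/trials/{trial_id}")
            d = g.create_dataset("accel", data=trace.samples)
            d.attrs["fs"] = trace.fs
            d.attrs["epoch_marks"] = trace.epoch_marks
            d.attrs["epoch_labels"] = list(trace.epoch_labels)
            series = cohort.roi[(subject_id, trial_id)]
            r = g.create_dataset("roi", data=series.samples)
            r.attrs["fs"] = series.fs
            r.attrs["epoch_marks"] = series.epoch_marks
            r.attrs["epoch_labels"] = list(series.epoch_labels)
            r.attrs["roi_labels"] = list(series.roi_labels)
            ref = cohort.tremor_reference.get((subject_id, trial_id))
            if ref is not None:
                g.create_dataset("reference", data=ref)
    cohort.trials.to_csv(csv_path, index=False, columns=list(TRIAL_COLUMNS))


def read_cohort(h5_path: str | Path, csv_path: str | Path) -> Cohort:
    accel: dict = {}
    roi: dict = {}
    references: dict = {}
    config = None
    with h5py.File(h5_path, "r") as f:
        if "config_json" in f.attrs:
            config = SynthConfig.from_dict(json.loads(f.attrs["config_json"]))
        for subject_id, sgrp in f["subjects"].items():
            for trial_key, g in sgrp["trials"].items():
                trial_id = int(trial_key)
                d = g["accel"]
                accel[(subject_id, trial_id)] = AccelTrace(
                    samples=d[()],
                    fs=float(d.attrs["fs"]),
                    epoch_marks=np.asarray(d.attrs["epoch_marks"]),
                    trial_id=f"{subject_id}_t{trial_id}",
                    epoch_labels=tuple(str(x) for x in d.attrs["epoch_labels"]),
                )
                r = g["roi"]
                roi[(subject_id, trial_id)] = RoiSeries(
                    samples=r[()],
                    fs=float(r.attrs["fs"]),
                    roi_labels=tuple(str(x) for x in r.attrs["roi_labels"]),
                    epoch_marks=np.asarray(r.attrs["epoch_marks"]),
                    trial_id=f"{subject_id}_t{trial_id}",
                    epoch_labels=tuple(str(x) for x in r.attrs["epoch_labels"]),
                )
                if "reference" in g:
                    references[(subject_id, trial_id)] = g["reference"][()]
    trials = pd.read_csv(csv_path)
    return Cohort(accel=accel, roi=roi, trials=trials, config=config,
                  tremor_reference=references)


def save_model(model: TfpcaModel, path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("coefficients", data=model.coefficients)
        f.create_dataset("latent", data=model.latent)
        f.create_dataset("explained_variance", data=model.explained_variance)
        f.create_dataset("column_means", data=model.column_means)
        f.create_dataset("freqs", data=model.freqs)
        f.attrs["roi_labels"] = list(model.roi_labels)
        f.attrs["epoch_bounds"] = json.dumps({k: list(v) for k, v in model.epoch_bounds.items()})
        f.attrs["total_variance"] = model.total_variance


def load_model(path: str | Path) -> TfpcaModel:
    with h5py.File(Path(path), "r") as f:
        bounds = {k: tuple(v) for k, v in json.loads(f.attrs["epoch_bounds"]).items()}
        return TfpcaModel(
            coefficients=f["coefficients"][()],
            latent=f["latent"][()],
            explained_variance=f["explained_variance"][()],
            column_means=f["column_means"][()],
            freqs=f["freqs"][()],
            roi_labels=tuple(str(x) for x in f.attrs["roi_labels"]),
            epoch_bounds=bounds,
            total_variance=float(f.attrs["total_variance"]),
        )


def write_tf_maps(maps: dict, path: str | Path) -> None:
    """Write nested TF maps to HDF5 as /<subject>/tf/<roi>/<epoch>.

    ``maps[subject][roi][epoch]`` must be :class:`~tremornet.datatypes.TFMap`;
    time and frequency axes are stored as datasets next to the values.
    """
    with h5py.File(Path(path), "w") as f:
        for subject, per_roi in maps.items():
            for roi, per_epoch in per_roi.items():
                for epoch, tfm in per_epoch.items():
                    g = f.require_group(f"{subject}/tf/{roi}/{epoch}")
                    g.create_dataset("values", data=tfm.values)
                    g.create_dataset("times", data=tfm.times)
                    g.create_dataset("freqs", data=tfm.freqs)
                    g.attrs["units"] = tfm.units


def read_tf_maps(path: str | Path) -> dict:
    from .datatypes import TFMap

    out: dict = {}
    with h5py.File(Path(path), "r") as f:
        for subject, sgrp in f.items():
            out[subject] = {}
            for roi, rgrp in sgrp["tf"].items():
                out[subject][roi] = {}
                for epoch, g in rgrp.items():
                    out[subject][roi][epoch] = TFMap(
                        values=g["values"][()], times=g["times"][()],
                        freqs=g["freqs"][()], units=str(g.attrs["units"]),
                    )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
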