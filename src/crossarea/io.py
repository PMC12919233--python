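"""Flat-directory session storage and pose-tracking CSV input.

A session directory holds:

- ``events.csv`` — the trial table, one row per trial.
- ``kinematics.csv`` — frame times plus x/y columns per tracked point
  (``wrist0..2``, ``thumb0..1``, ``index0..1``).
- ``arrays.h5`` — spike times (one ragged dataset per channel under
  ``spikes/<area>/ch<i>``), optional voltage, and ground-truth latents /
  loadings for synthetic sessions.
- ``config.json`` — the generating configuration, when synthetic.

Pose CSVs in the DeepLabCut dialect (3-row scorer/bodyparts/coords header
with x, y, likelihood columns) are read with a per-point likelihood
acceptance threshold (default 0.9; below it the sample is missing).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List

import h5py
import numpy as np
import pandas as pd

from .containers import KinematicTrace, TrialTable
from .dlag import DLAGModel, FittedLatentSpec

__all__ = ["save_session", "load_trial_table", "load_spike_times",
           "read_dlc_csv", "save_model", "load_model"]


def save_session(session, out_dir) -> Path:
    """Write a (synthetic) session to the flat CSV + HDF5 directory schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trial_table.df.to_csv(out / "events.csv", index=False)

    kin = session.kinematics
    cols = {"frame_time": kin.frame_times}
    names = ["wrist0", "wrist1", "wrist2"]
    for k, name in enumerate(names):
        cols[f"{name}_x"] = kin.wrist_points[:, k, 0]
        cols[f"{name}_y"] = kin.wrist_points[:, k, 1]
    for k, name in enumerate(["thumb0", "thumb1", "index0", "index1"]):
        cols[f"{name}_x"] = kin.digit_points[:, k, 0]
        cols[f"{name}_y"] = kin.digit_points[:, k, 1]
    pd.DataFrame(cols).to_csv(out / "kinematics.csv", index=False)

    with h5py.File(out / "arrays.h5", "w") as f:
        for area, chans in session.spike_times.items():
            g = f.create_group(f"spikes/{area}")
            for i, st in enumerate(chans):
                g.create_dataset(f"ch{i}", data=np.asarray(st))
        if session.voltage is not None:
            for area, v in session.voltage.items():
                f.create_dataset(f"voltage/{area}", data=v)
            f.attrs["voltage_fs"] = session.voltage_fs
            f.attrs["voltage_t0"] = session.voltage_t0
        gt = session.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            for name in ("cf_A", "cf_B", "wf_A", "wf_B", "bin_grid"):
                g.create_dataset(name, data=getattr(gt.latents, name))
            g.create_dataset("loadings_A", data=gt.loadings_A)
            g.create_dataset("loadings_B", data=gt.loadings_B)

    cfg = dataclasses.asdict(session.config)
    (out / "config.json").write_text(json.dumps(cfg, default=_jsonable,
                                                indent=1))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_trial_table(session_dir) -> TrialTable:
    df = pd.read_csv(Path(session_dir) / "events.csv")
    return TrialTable(df)


def load_spike_times(session_dir, area: str) -> List[np.ndarray]:
    with h5py.File(Path(session_dir) / "arrays.h5", "r") as f:
        g = f[f"spikes/{area}"]
        return [g[f"ch{i}"][()] for i in range(len(g))]


def read_dlc_csv(path, likelihood_threshold: float = 0.9,
                 wrist_parts=("wrist0", "wrist1", "wrist2"),
                 thumb_parts=("thumb0", "thumb1"),
                 index_parts=("index0", "index1")) -> KinematicTrace:
    """Read a DeepLabCut-dialect pose CSV into a KinematicTrace.

    Expects the 3-row header (scorer / bodyparts / coords) with x, y and
    likelihood per bodypart; samples below the likelihood threshold are
    set missing.  Frame times are taken from a ``frame_time`` column when
    present (under any scorer), else synthesized at 50 fps.
    """
    df = pd.read_csv(path, header=[0, 1, 2])
    bodyparts = df.columns.get_level_values(1)

    def get(part, coord):
        col = df.loc[:, (slice(None), part, coord)]
        return col.iloc[:, 0].to_numpy(dtype=float)

    def point(part):
        x, y = get(part, "x").copy(), get(part, "y").copy()
        try:
            lik = get(part, "likelihood")
        except (KeyError, IndexError):
            lik = None
        if lik is not None:
            bad = lik < likelihood_threshold
            x[bad] = np.nan
            y[bad] = np.nan
        return np.column_stack([x, y])

    F = len(df)
    if "frame_time" in set(bodyparts):
        frame_times = df.loc[:, (slice(None), "frame_time")].iloc[:, 0].to_numpy(float)
    else:
        frame_times = np.arange(F) / 50.0
    wrist = np.stack([point(p) for p in wrist_parts], axis=1)
    digits = np.stack([point(p) for p in (*thumb_parts, *index_parts)], axis=1)
    return KinematicTrace(frame_times=frame_times, wrist_points=wrist,
                          digit_points=digits)


def save_model(model: DLAGModel, path) -> Path:
    """Serialize a fitted model to a single JSON bundle."""
    path = Path(path)
    payload = {
        "loadings_A": model.loadings_A.tolist(),
        "loadings_B": model.loadings_B.tolist(),
        "offset_A": model.offset_A.tolist(),
        "offset_B": model.offset_B.tolist(),
        "noise_A": model.noise_A.tolist(),
        "noise_B": model.noise_B.tolist(),
        "dims": list(model.dims),
        "bin_width": model.bin_width,
        "fit_log": list(map(float, model.fit_log)),
        "converged": model.converged,
        "latent_specs": [dataclasses.asdict(s) for s in model.latent_specs],
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> DLAGModel:
    d = json.loads(Path(path).read_text())
    return DLAGModel(
        loadings_A=np.asarray(d["loadings_A"]),
        loadings_B=np.asarray(d["loadings_B"]),
        offset_A=np.asarray(d["offset_A"]),
        offset_B=np.asarray(d["offset_B"]),
        noise_A=np.asarray(d["noise_A"]),
        noise_B=np.asarray(d["noise_B"]),
        latent_specs=[FittedLatentSpec(**s) for s in d["latent_specs"]],
        dims=tuple(d["dims"]), bin_width=d["bin_width"],
        fit_log=d["fit_log"], converged=d["converged"])
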