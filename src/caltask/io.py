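"""Readers and writers for the package's on-disk formats.

Trial tables travel as CSV, trace tensors as HDF5 (datasets /dff, /raw_dff,
/time_s plus trial metadata), movies and mask images as (multi-page) TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import Movie, TrialAlignedTraces, TRIAL_COLUMNS

PathLike = Union[str, Path]


def write_trial_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False,
                        dtype={"laser_epoch": str})
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    table["licked"] = table["licked"].astype(bool)
    table["laser_on"] = table["laser_on"].astype(bool)
    return table


def write_traces(traces: TrialAlignedTraces, path: PathLike,
                 truth=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=traces.dff, compression="gzip")
        if traces.raw_dff is not None:
            f.create_dataset("raw_dff", data=traces.raw_dff,
                             compression="gzip")
        f.create_dataset("time_s", data=traces.time_s)
        f.attrs["baseline_window"] = traces.baseline_window
        grp = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = traces.table[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)
        if truth is not None:
            g = f.create_group("ground_truth")
            for name in ("archetype", "preferred"):
                v = getattr(truth, name)
                if v is not None:
                    g.create_dataset(name, data=np.asarray(v, dtype="S"))
            for name in ("amplitude", "selectivity", "onset_latency"):
                v = getattr(truth, name)
                if v is not None:
                    g.create_dataset(name, data=np.asarray(v, dtype=float))


def read_traces(path: PathLike) -> TrialAlignedTraces:
    with h5py.File(path, "r") as f:
        dff = f["dff"][()]
        raw = f["raw_dff"][()] if "raw_dff" in f else None
        time_s = f["time_s"][()]
        baseline = tuple(f.attrs["baseline_window"])
        cols = {}
        for col in TRIAL_COLUMNS:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        table = pd.DataFrame(cols)
    table["licked"] = table["licked"].astype(bool)
    table["laser_on"] = table["laser_on"].astype(bool)
    return TrialAlignedTraces(dff=dff, time_s=time_s, table=table,
                              raw_dff=raw, baseline_window=baseline)


def write_movie(movie: Movie, path: PathLike) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))


def read_movie(path: PathLike, frame_rate: float = 5.0,
               pixel_size: float = 1.0, plane: int = 0) -> Movie:
    frames = tifffile.imread(path).astype(float)
    return Movie(frames=frames, frame_rate=frame_rate,
                 pixel_size=pixel_size, plane=plane)


def write_mask_image(labels: np.ndarray, path: PathLike) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_mask_image(path: PathLike) -> np.ndarray:
    return tifffile.imread(path)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
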