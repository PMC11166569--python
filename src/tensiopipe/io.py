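"""Readers and writers for the plain-text and image formats used throughout.

Cell-record tables and TCSPC histograms travel as CSV, movies and FLIM
stacks as multi-page TIFF with a JSON sidecar, fits as JSON, and simulator
states as HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .activation import RECORD_COLUMNS
from .flim import TCSPCHistogram

__all__ = [
    "write_records",
    "read_records",
    "write_tcspc",
    "read_tcspc",
    "write_movie",
    "read_movie",
    "write_json",
    "read_json",
    "save_system",
    "load_system",
]


def write_records(records: pd.DataFrame, path) -> None:
    records.loc[:, RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file is missing columns: {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_tcspc(h: TCSPCHistogram, path, irf_path=None) -> None:
    pd.DataFrame({"time_ns": h.time_ns, "counts": h.counts}).to_csv(path, index=False)
    if irf_path is not None:
        pd.DataFrame({"time_ns": h.time_ns, "counts": h.irf_counts}).to_csv(
            irf_path, index=False
        )


def read_tcspc(path, irf_path=None) -> TCSPCHistogram:
    df = pd.read_csv(path)
    if irf_path is not None:
        irf = pd.read_csv(irf_path)["counts"].to_numpy()
    else:
        irf = np.zeros(len(df))
        irf[np.argmax(df["counts"].to_numpy())] = 1.0  # crude delta fallback
    return TCSPCHistogram(
        time_ns=df["time_ns"].to_numpy(), counts=df["counts"].to_numpy(),
        irf_counts=irf,
    )


def write_movie(movie: np.ndarray, path, *, pixel_size_um: float,
                frame_interval_s: float, channels=("green",)) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    sidecar = {
        "pixel_size_um": pixel_size_um,
        "frame_interval_s": frame_interval_s,
        "channels": list(channels),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    movie = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return np.asarray(movie), meta


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_system(system, state, path) -> None:
    """Persist a simulator system + load state to HDF5."""
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        g = f.create_group("system")
        for name in ("positions", "ref_positions", "triangles", "edges",
                     "rest_lengths", "fixed", "ring", "inside", "anchors",
                     "anchor_points", "vertex_area"):
            g.create_dataset(name, data=getattr(system, name))
        g.attrs["config"] = json.dumps(asdict(system.config))
        if state is not None:
            s = f.create_group("state")
            for key, val in asdict(state).items():
                if isinstance(val, np.ndarray):
                    s.create_dataset(key, data=val)
                elif val is not None:
                    s.attrs[key] = val


def load_system(path):
    from .cgtension import CgConfig, LoadState, MembraneSystem

    with h5py.File(path, "r") as f:
        g = f["system"]
        cfg_dict = json.loads(g.attrs["config"])
        config = CgConfig(**cfg_dict)
        system = MembraneSystem(
            config=config,
            positions=g["positions"][...],
            ref_positions=g["ref_positions"][...],
            triangles=g["triangles"][...],
            edges=g["edges"][...],
            rest_lengths=g["rest_lengths"][...],
            fixed=g["fixed"][...].astype(bool),
            ring=g["ring"][...].astype(bool),
            inside=g["inside"][...].astype(bool),
            anchors=g["anchors"][...].astype(int),
            anchor_points=g["anchor_points"][...],
            vertex_area=g["vertex_area"][...],
        )
        state = None
        if "state" in f:
            s = f["state"]
            state = LoadState(
                force_nN=s.attrs.get("force_nN"),
                ring_depth_um=s.attrs.get("ring_depth_um"),
                pressure_mbar=s.attrs.get("pressure_mbar", 0.0),
                converged=bool(s.attrs.get("converged", False)),
                residual=float(s.attrs.get("residual", np.nan)),
                achieved_force_nN=float(s.attrs.get("achieved_force_nN", np.nan)),
            )
    return system, state
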