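"""Reading and writing of localization, track, event and titration tables.

Conventions (declared in every file header): coordinates in micrometers with
origin at the lower-left corner of the field of view, 0-based frame indices,
times in seconds. CSV is the canonical interchange format; HDF5 mirrors it
for large runs with a `metadata` group. Pixel-unit input is converted with
an effective pixel size of 0.108 um when declared.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .linking import TrackSet

__all__ = [
    "PIXEL_SIZE_UM",
    "read_localizations",
    "write_localizations",
    "read_tracks",
    "write_tracks",
    "write_events",
    "read_titration",
    "write_titration",
]

log = logging.getLogger("paintspt")

PIXEL_SIZE_UM = 0.108

_LOC_REQUIRED = ["frame"]
_HEADER = ("paintspt localization table; units um, origin lower-left, "
           "0-based frames")


def _is_hdf5(path) -> bool:
    return str(path).lower().endswith((".h5", ".hdf5"))


def _csv_metadata(path) -> dict:
    md = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, _, v = line[1:].partition("=")
                try:
                    md[k.strip()] = json.loads(v.strip())
                except (json.JSONDecodeError, ValueError):
                    md[k.strip()] = v.strip()
    return md


def _write_csv(df: pd.DataFrame, path, metadata: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_HEADER}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {json.dumps(v, default=str)}\n")
        df.to_csv(fh, index=False)


def _write_hdf5(df: pd.DataFrame, path, metadata: dict, group: str) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group(group)
        for col in df.columns:
            data = df[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        m = f.create_group("metadata")
        m.attrs["header"] = _HEADER
        for k, v in (metadata or {}).items():
            try:
                m.attrs[k] = v
            except TypeError:
                m.attrs[k] = json.dumps(v, default=str)


def _read_hdf5(path, group: str):
    with h5py.File(path, "r") as f:
        g = f[group]
        df = pd.DataFrame({k: g[k][...] for k in g.keys()})
        md = dict(f["metadata"].attrs) if "metadata" in f else {}
    for k, v in list(md.items()):
        if isinstance(v, bytes):
            md[k] = v.decode()
        if isinstance(md[k], str) and md[k][:1] in "{[":
            try:
                md[k] = json.loads(md[k])
            except json.JSONDecodeError:
                pass
    return df, md


def write_localizations(df: pd.DataFrame, path, metadata: dict = None) -> None:
    """Write a localization table (CSV or HDF5 by extension).

    Internal columns (frame, x, y, sigma, channel[, truth_id]) are stored as
    (frame, x_um, y_um, sigma_um, channel, truth_id).
    """
    md = dict(df.attrs.get("metadata", {}))
    md.update(metadata or {})
    md.setdefault("pixel_size_um", PIXEL_SIZE_UM)
    out = df.rename(columns={"x": "x_um", "y": "y_um", "sigma": "sigma_um"})
    keep = [c for c in ["frame", "x_um", "y_um", "sigma_um", "channel",
                        "truth_id", "loc_id"] if c in out.columns]
    out = out[keep]
    if _is_hdf5(path):
        _write_hdf5(out, path, md, "localizations")
    else:
        _write_csv(out, path, md)


def read_localizations(path, pixel_size: float = None) -> pd.DataFrame:
    """Read a localization table; returns internal-unit columns
    (frame, x, y, sigma, channel, truth_id) with metadata in ``df.attrs``.

    Coordinates may be given as x_um/y_um (micrometers) or x_px/y_px (pixels,
    converted using `pixel_size` or the pixel_size_um metadata entry).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_hdf5(path):
        df, md = _read_hdf5(path, "localizations")
    else:
        md = _csv_metadata(path)
        df = pd.read_csv(path, comment="#")
    for col in _LOC_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    if "x_um" in df.columns:
        df = df.rename(columns={"x_um": "x", "y_um": "y"})
    elif "x_px" in df.columns:
        px = pixel_size if pixel_size is not None else md.get("pixel_size_um")
        if px is None:
            raise ValueError(
                "pixel-unit coordinates (x_px/y_px) but no pixel size: pass "
                "pixel_size= or declare pixel_size_um in the file metadata")
        df["x"] = df.pop("x_px") * float(px)
        df["y"] = df.pop("y_px") * float(px)
    elif "x" not in df.columns:
        raise ValueError(f"missing required column 'x_um' (or 'x_px') in {path}")
    if "sigma_um" in df.columns:
        df = df.rename(columns={"sigma_um": "sigma"})
    if "sigma" not in df.columns:
        df["sigma"] = np.nan
    if "channel" not in df.columns:
        df["channel"] = 1
    if len(df) == 0:
        warnings.warn(f"empty localization table: {path}")
        log.warning("empty localization table: %s", path)
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    df.attrs["metadata"] = md
    return df


def write_tracks(ts: TrackSet, path) -> None:
    """Write a track table (track_id, channel, frame, x_um, y_um, loc_id)."""
    out = ts.table.rename(columns={"x": "x_um", "y": "y_um"})
    md = dict(ts.metadata)
    md["dt"] = ts.dt
    if _is_hdf5(path):
        _write_hdf5(out, path, md, "tracks")
    else:
        _write_csv(out, path, md)


def read_tracks(path) -> TrackSet:
    if _is_hdf5(path):
        df, md = _read_hdf5(path, "tracks")
    else:
        md = _csv_metadata(path)
        df = pd.read_csv(path, comment="#")
    df = df.rename(columns={"x_um": "x", "y_um": "y"})
    for col in ("track_id", "frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    if "channel" not in df.columns:
        df["channel"] = 1
    if "loc_id" not in df.columns:
        df["loc_id"] = np.arange(len(df))
    dt = md.get("dt")
    if dt is None:
        raise ValueError(f"track file {path} lacks dt metadata")
    return TrackSet(table=df, dt=float(dt), metadata=md)


def write_events(result, path) -> None:
    """Write accepted co-diffusion events
    (event_id, track_ch1, track_ch2, start_frame, end_frame, n_coloc,
    duration_s)."""
    df = result.to_frame()
    md = {"R": result.params.R, "G_max": result.params.G_max,
          "N_min": result.params.N_min, "dt": result.dt,
          "n_rejected_episodes": result.n_rejected_episodes,
          "n_orphan_pairs": result.n_orphan_pairs}
    if _is_hdf5(path):
        _write_hdf5(df, path, md, "events")
    else:
        _write_csv(df, path, md)


def write_titration(df: pd.DataFrame, path, metadata: dict = None) -> None:
    """Write a titration table (ligand_M, fraction, sd, n)."""
    _write_csv(df, path, metadata or {})


def read_titration(path) -> pd.DataFrame:
    md = _csv_metadata(path)
    df = pd.read_csv(path, comment="#")
    for col in ("ligand_M", "fraction"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    df.attrs["metadata"] = md
    return df
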