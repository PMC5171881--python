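"""Readers and writers for trajectory tables, localization tables and
generic result tables.

Trajectory TSV contract: columns ``track_id, frame, x, y`` (optional
``field_id``); comment lines start with ``#``; a ``# units: um`` or
``# units: nm`` header line is required unless the caller declares the
units — silent unit guessing is forbidden. Localization CSV: columns
``frame, x_nm, y_nm`` (ThunderSTORM-style ``x [nm]`` headers accepted),
optional ``precision_nm``/``intensity``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .locs import LocalizationTable
from .tracks import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_localizations",
    "write_localizations",
    "write_table",
]

_TRAJ_COLUMNS = ("track_id", "frame", "x", "y")

# header aliases seen in common SMLM table exports
_LOC_ALIASES = {
    "frame": "frame",
    "x_nm": "x", "x [nm]": "x", "x": "x",
    "y_nm": "y", "y [nm]": "y", "y": "y",
    "precision_nm": "precision", "uncertainty [nm]": "precision",
    "uncertainty_xy [nm]": "precision", "precision": "precision",
    "intensity": "intensity", "intensity [photon]": "intensity",
}


def _read_header_comments(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip().lower()] = val.strip()
    return meta


def read_trajectories(path, dt=None, units=None):
    """Read a trajectory table into a list of :class:`Trajectory`.

    Parameters
    ----------
    path : path-like
        TSV or CSV file with columns ``track_id, frame, x, y``
        (+ optional ``field_id``); ``#``-prefixed comment lines may carry
        ``# units: um|nm`` and ``# dt: <seconds>``.
    dt : float, optional
        Frame interval in seconds; overrides any ``# dt`` header. Defaults
        to the header value or 1/33 s.
    units : {"um", "nm"}, optional
        Position units; overrides the ``# units`` header. One of the two
        sources is mandatory.

    Returns
    -------
    list of Trajectory
        Positions normalized to μm, frames sorted. Tracks containing
        duplicate frame indices are dropped with a warning (a tracker
        cannot legitimately emit them), as are single-point tracks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_header_comments(path)
    if units is None:
        units = meta.get("units")
    if units not in ("um", "nm"):
        raise ValueError(
            f"{path}: position units undeclared; add a '# units: um|nm' "
            "header line or pass units= explicitly"
        )
    if dt is None:
        dt = float(meta.get("dt", 1.0 / 33.0))

    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] == 1 and sep == ",":  # tolerate tab-separated .csv
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    scale = 1e-3 if units == "nm" else 1.0
    has_field = "field_id" in df.columns
    tracks = []
    n_dropped = 0
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if len(frames) < 2:
            n_dropped += 1
            continue
        if np.any(np.diff(frames) == 0):
            log.warning("track %s: duplicate frame indices, track dropped", tid)
            n_dropped += 1
            continue
        tracks.append(Trajectory(
            track_id=str(tid),
            frames=frames,
            x=grp["x"].to_numpy(dtype=np.float64) * scale,
            y=grp["y"].to_numpy(dtype=np.float64) * scale,
            dt=dt,
            field_id=str(grp["field_id"].iloc[0]) if has_field else "field0",
        ))
    if n_dropped:
        log.warning("%s: dropped %d invalid track(s)", path, n_dropped)
    return tracks


def write_trajectories(tracks, path, units="um") -> None:
    """Write trajectories as TSV with the standard header comments."""
    if units not in ("um", "nm"):
        raise ValueError("units must be 'um' or 'nm'")
    scale = 1e3 if units == "nm" else 1.0
    path = Path(path)
    rows = []
    for tr in tracks:
        for f, xx, yy in zip(tr.frames, tr.x, tr.y):
            rows.append((tr.track_id, int(f), xx * scale, yy * scale, tr.field_id))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "field_id"])
    dt = tracks[0].dt if tracks else 1.0 / 33.0
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n# dt: {dt:.12g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9f")


def read_localizations(path, fov=None, pixel_size_camera=100.0) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable` (nm).

    ThunderSTORM-style headers (``x [nm]`` etc.) are mapped to the internal
    names. The field of view defaults to the data extent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty localization file")
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _LOC_ALIASES:
            renames[col] = _LOC_ALIASES[key]
    df = df.rename(columns=renames)
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} "
                             "(expected frame, x_nm, y_nm)")
    keep = [c for c in ("frame", "x", "y", "precision", "intensity")
            if c in df.columns]
    return LocalizationTable(df=df[keep], fov=fov,
                             pixel_size_camera=pixel_size_camera)


def write_localizations(table: LocalizationTable, path) -> None:
    df = table.df.rename(columns={"x": "x_nm", "y": "y_nm",
                                  "precision": "precision_nm"})
    with open(path, "w") as fh:
        xmin, xmax, ymin, ymax = table.fov
        fh.write(f"# fov_nm: {xmin:.6f} {xmax:.6f} {ymin:.6f} {ymax:.6f}\n")
        fh.write(f"# pixel_size_camera_nm: {table.pixel_size_camera:.6f}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def write_table(result, path) -> None:
    """Write any result object as a plain-text table.

    ``result`` may be a DataFrame or any object exposing ``to_frame()``.
    Column order is whatever the object defines; floats use a fixed
    ``%.9g`` format so identical inputs give byte-identical files.
    """
    if hasattr(result, "to_frame"):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    elif isinstance(result, pd.Series):
        df = result.to_frame().T
    else:
        raise TypeError(f"cannot tabulate object of type {type(result).__name__}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.9g")
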