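"""Localization tables for the single-molecule localization (SMLM) arm.

Coordinates are stored in nm. The table wraps a pandas DataFrame with
columns ``frame, x, y`` plus optional ``precision`` and ``intensity``; the
rectangular field of view and the camera pixel size travel with the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LocalizationTable"]

REQUIRED_COLUMNS = ("frame", "x", "y")


@dataclass
class LocalizationTable:
    """Point detections from an SMLM acquisition, coordinates in nm.

    Attributes
    ----------
    df : DataFrame
        Columns ``frame`` (int, ≥ 0), ``x``, ``y`` (nm); optional
        ``precision`` (nm, > 0) and ``intensity``.
    fov : tuple
        ``(xmin, xmax, ymin, ymax)`` in nm. Inferred from the data extent
        when not given.
    pixel_size_camera : float
        Camera pixel size in nm, needed to interpret pixel-unit distances
        such as the consolidation radius.
    """

    df: pd.DataFrame
    fov: tuple = None
    pixel_size_camera: float = 100.0

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"localization table missing column {col!r}")
        df = df.copy()
        df["frame"] = df["frame"].astype(np.int64)
        df["x"] = df["x"].astype(np.float64)
        df["y"] = df["y"].astype(np.float64)
        if (df["frame"] < 0).any():
            raise ValueError("localization frames must be >= 0")
        if "precision" in df.columns:
            prec = df["precision"].astype(np.float64)
            if (prec[prec.notna()] <= 0).any():
                raise ValueError("localization precision must be > 0")
            df["precision"] = prec
        if self.fov is None:
            if len(df):
                self.fov = (
                    float(df["x"].min()), float(df["x"].max()),
                    float(df["y"].min()), float(df["y"].max()),
                )
            else:
                self.fov = (0.0, 0.0, 0.0, 0.0)
        else:
            self.fov = tuple(float(v) for v in self.fov)
            xmin, xmax, ymin, ymax = self.fov
            if len(df):
                inside = (
                    (df["x"] >= xmin) & (df["x"] <= xmax)
                    & (df["y"] >= ymin) & (df["y"] <= ymax)
                )
                if not inside.all():
                    raise ValueError(
                        f"{int((~inside).sum())} localizations outside the "
                        "declared fov"
                    )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) position array in nm."""
        return self.df[["x", "y"]].to_numpy()

    @property
    def area_nm2(self) -> float:
        xmin, xmax, ymin, ymax = self.fov
        return (xmax - xmin) * (ymax - ymin)

    @property
    def area_um2(self) -> float:
        return self.area_nm2 * 1e-6

    def density_um2(self) -> float:
        """Average localization density over the fov, μm⁻²."""
        if self.area_um2 == 0:
            return float("nan")
        return len(self) / self.area_um2

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        """New table sharing fov/camera metadata but different records."""
        return LocalizationTable(
            df=df, fov=self.fov, pixel_size_camera=self.pixel_size_camera
        )
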