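"""Canonical in-memory container for localization tables.

A localization table is a point cloud of single-fluorophore detections.
Internally it is a :class:`pandas.DataFrame` with fixed column names
(all distances in nanometres, frames 0-based) wrapped together with the
field of view, the camera pixel size and free-form provenance metadata.

Columns
-------
x, y : float
    Lateral position (nm), origin at the field-of-view corner, x right,
    y down.
z : float, optional
    Axial position (nm), away from the coverslip.  Absent before the
    astigmatic lookup has been applied.
frame : int
    0-based acquisition frame index within the source movie.
movie_id : int
    Index of the source movie / axial scan.
intensity, background : float
    Fitted amplitude and local background in camera units.
width_x, width_y : float
    Fitted PSF standard deviations (nm); the x/y asymmetry encodes the
    axial position under astigmatic imaging.
channel : str
    Staining-round label ("bassoon", "gfp", "bead", ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Column order used by the canonical CSV dialect (``z`` optional).
CORE_COLUMNS = ("x", "y", "z", "frame", "movie_id", "intensity",
                "background", "width_x", "width_y", "channel")

#: Columns that must be present in every table.
MANDATORY_COLUMNS = ("x", "y", "frame")


@dataclass
class LocalizationTable:
    """Ordered collection of localizations sharing one coordinate frame.

    Parameters
    ----------
    df : pandas.DataFrame
        Localization records; see module docstring for column semantics.
        Record order is meaningful and preserved by every operation.
    field_of_view : tuple of float
        Lateral extents ``(x_extent, y_extent)`` in nm.
    pixel_size : float
        Camera pixel size in nm (used only for pixel-unit dialects).
    metadata : dict
        Free-form provenance: dialect, source file, filters applied, ...
    """

    df: pd.DataFrame
    field_of_view: tuple[float, float] = (25_000.0, 25_000.0)
    pixel_size: float = 126.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParameterError(f"localization table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_z(self) -> bool:
        return "z" in self.df.columns

    @property
    def has_widths(self) -> bool:
        return "width_x" in self.df.columns and "width_y" in self.df.columns

    def coords(self, dims: str = "xyz") -> np.ndarray:
        """Return an ``(n, len(dims))`` float array of coordinates."""
        return self.df[list(dims)].to_numpy(dtype=float)

    def replace(self, df: pd.DataFrame, **metadata_updates) -> "LocalizationTable":
        """New table with the same frame-of-reference but different records."""
        meta = dict(self.metadata)
        meta.update(metadata_updates)
        return LocalizationTable(df=df.reset_index(drop=True),
                                 field_of_view=self.field_of_view,
                                 pixel_size=self.pixel_size,
                                 metadata=meta)


def concat_tables(tables: Iterable[LocalizationTable]) -> LocalizationTable:
    """Concatenate tables that share one coordinate frame, keeping order."""
    tables = list(tables)
    if not tables:
        raise ParameterError("no tables to concatenate")
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return tables[0].replace(df, concatenated=len(tables))


def filter_intensity(table: LocalizationTable, threshold: float) -> LocalizationTable:
    """Keep localizations with fitted intensity >= ``threshold``.

    The inclusive comparison means a localization exactly at the threshold
    survives.  The raw-data analysis this mirrors used a threshold of
    10000 camera units to suppress out-of-focus background in thick
    epi-illuminated samples.
    """
    if threshold < 0:
        raise ParameterError(f"intensity threshold must be >= 0, got {threshold}")
    if "intensity" not in table.df.columns:
        raise ParameterError("table has no intensity column")
    keep = table.df["intensity"].to_numpy() >= threshold
    out = table.df.loc[keep]
    return table.replace(out, intensity_threshold=float(threshold),
                         intensity_removed=int((~keep).sum()))


def render_histogram_2d(table: LocalizationTable, bin_size: float) -> np.ndarray:
    """Bin localizations laterally into a 2D count image.

    Bins are half-open ``[k*b, (k+1)*b)``; the image has
    ``ceil(extent / bin_size)`` pixels per axis (x first axis, y second).
    The image sum equals the number of records inside the field of view.
    """
    if bin_size <= 0:
        raise ParameterError(f"bin_size must be > 0, got {bin_size}")
    ex, ey = table.field_of_view
    nx = max(1, math.ceil(ex / bin_size))
    ny = max(1, math.ceil(ey / bin_size))
    x = table.df["x"].to_numpy(dtype=float)
    y = table.df["y"].to_numpy(dtype=float)
    inside = (x >= 0) & (x < ex) & (y >= 0) & (y < ey)
    ix = np.floor(x[inside] / bin_size).astype(np.intp)
    iy = np.floor(y[inside] / bin_size).astype(np.intp)
    img = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(img, (ix, iy), 1)
    return img
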