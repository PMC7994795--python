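"""Continuous axial scan geometry and volumetric assembly.

The acquisition records several movies while a piezo stage moves the
sample axially at constant speed through the objective's focal plane,
inverting the direction of travel after each scan so that the end of one
movie coincides with the start of the next.  A localization fitted in
frame ``f`` of scan ``k`` therefore sits at a known stage position, and
its true axial coordinate is that stage position plus the astigmatic
offset looked up from its PSF widths.

At the default 100 Hz and 10 um per 15,000-frame movie the stage travels
~0.67 nm within one frame, far below localization precision, so each
localization is attributed to its frame's stage position without motion
blur correction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .calibration import ZCalibration
from .errors import ParameterError, SpecMismatchError
from .table import LocalizationTable, concat_tables


@dataclass
class ScanSpec:
    """Acquisition geometry of a repeated axial scan.

    z_travel is in micrometres (10 by default; 6 was used for the
    Forskolin protocol); everything else in frames, Hz or nm.
    """

    n_scans: int = 10
    frames_per_movie: int = 15_000
    frame_rate: float = 100.0
    z_travel: float = 10.0
    z_start: float = 0.0
    alternate_direction: bool = True

    def __post_init__(self) -> None:
        if self.z_travel <= 0:
            raise ParameterError("z_travel must be > 0")
        if self.frames_per_movie < 2:
            raise ParameterError("frames_per_movie must be >= 2")
        if self.n_scans < 1:
            raise ParameterError("n_scans must be >= 1")

    @property
    def z_travel_nm(self) -> float:
        return self.z_travel * 1000.0

    @property
    def total_frames(self) -> int:
        return self.n_scans * self.frames_per_movie

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanSpec":
        return cls(**d)


def stage_z(frame, scan_index, spec: ScanSpec):
    """Stage position (nm) for frame(s) of a given scan.

    Ascending scans run linearly from ``z_start`` to
    ``z_start + z_travel`` with a ``frames_per_movie - 1`` denominator so
    both endpoints are reached; with direction alternation, odd scans
    mirror the trajectory so consecutive scans join seamlessly.
    """
    frame = np.asarray(frame)
    scan_index = np.asarray(scan_index)
    if np.any(frame < 0) or np.any(frame >= spec.frames_per_movie):
        raise ParameterError("frame index out of range for this ScanSpec")
    if np.any(scan_index < 0) or np.any(scan_index >= spec.n_scans):
        raise ParameterError("scan index out of range for this ScanSpec")
    frac = frame / (spec.frames_per_movie - 1)
    if spec.alternate_direction:
        descending = scan_index % 2 == 1
        frac = np.where(descending, 1.0 - frac, frac)
    z = spec.z_start + spec.z_travel_nm * frac
    return z if z.shape else float(z)


def global_time_fraction(frame, movie_id, spec: ScanSpec):
    """Fraction t in [0, 1] of the whole acquisition at (movie, frame)."""
    gf = np.asarray(movie_id) * spec.frames_per_movie + np.asarray(frame)
    return gf / (spec.total_frames - 1)


def assemble_volume(movies: list[LocalizationTable], spec: ScanSpec,
                    calib: ZCalibration) -> LocalizationTable:
    """Merge per-scan movies into one volumetric table with true z.

    For every localization, ``z = stage_z(frame, scan) + astigmatic
    offset`` from the width lookup.  Localizations whose lookup residual
    exceeds the calibration's rejection ceiling are dropped; their tally
    is recorded in the output metadata so that counts stay auditable
    (kept + rejected equals the input total).
    """
    if len(movies) != spec.n_scans:
        raise SpecMismatchError(
            f"got {len(movies)} movies but spec declares {spec.n_scans} scans")
    parts = []
    n_rejected = 0
    for k, movie in enumerate(movies):
        df = movie.df.copy()
        if not movie.has_widths:
            raise ParameterError("movie lacks PSF width columns; "
                                 "z lookup is impossible")
        look = calib.predict(df[["width_x", "width_y"]])
        keep = ~look["rejected"].to_numpy()
        n_rejected += int((~keep).sum())
        z = stage_z(df["frame"].to_numpy(), k, spec) + look["z"].to_numpy()
        df["z"] = z
        df["movie_id"] = k
        df["z_residual"] = look["residual"].to_numpy()
        parts.append(movie.replace(df.loc[keep]))
    out = concat_tables(parts)
    out.metadata.update(n_rejected=n_rejected, scan_spec=spec.to_dict(),
                        n_input=sum(len(m) for m in movies))
    return out
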