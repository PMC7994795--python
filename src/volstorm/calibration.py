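"""Astigmatic width-vs-z calibration and axial lookup.

Under astigmatic 3D imaging a cylindrical lens makes the fitted PSF
widths ``width_x`` and ``width_y`` asymmetric functions of defocus: one
focuses above, the other below the nominal focal plane.  Calibration
sweeps a fluorescent-bead sample axially at constant speed, records the
fitted widths against the known stage position, and smooths both
width-vs-z relations with cubic smoothing splines.  The axial position of
a sample localization is then the ``z`` whose calibrated width pair best
matches the fitted widths.

The lookup minimizes the squared width-space distance to the paired
curves, ``(wx(z) - width_x)^2 + (wy(z) - width_y)^2``, rather than
inverting the width difference: this stays robust when only one width is
noisy.  The calibration is valid only on the interval where the
discriminant ``d(z) = wx(z) - wy(z)`` is strictly monotone, which makes
the lookup unique; the focal plane is the root of ``d``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline, make_smoothing_spline
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .errors import CalibrationError, DataError, ParameterError
from .table import LocalizationTable

#: Default residual ceiling (nm in width space) above which a lookup is
#: flagged rejected rather than trusted.
DEFAULT_REJECTION_CEILING = 50.0


class ZCalibration(BaseEstimator):
    """Width-vs-z calibration table with least-squares axial lookup.

    Parameters
    ----------
    smoothing : float or None
        Smoothing penalty ``lam`` of the cubic smoothing spline; ``None``
        selects it by generalized cross-validation, which in practice
        leaves a residual RMS close to the width noise.
    bin_width : float
        Stage-z bin width (nm) used to average widths before the spline
        fit; calibration stacks localize many beads per frame.
    grid_step : float
        Step (nm) of the cached lookup grid.
    rejection_ceiling : float
        Width-space residual (nm) above which :meth:`predict` flags a
        localization as rejected.

    Attributes
    ----------
    wx_spline_, wy_spline_ : scipy.interpolate.BSpline
        Smoothed width curves (nm vs stage z in nm).
    z_range_ : tuple of float
        Interval of validity, trimmed to where the discriminant is
        strictly monotone.
    focal_z_ : float
        Stage z where the two width curves cross (the focal plane).
    """

    def __init__(self, smoothing: float | None = None, bin_width: float = 10.0,
                 grid_step: float = 1.0,
                 rejection_ceiling: float = DEFAULT_REJECTION_CEILING):
        self.smoothing = smoothing
        self.bin_width = bin_width
        self.grid_step = grid_step
        self.rejection_ceiling = rejection_ceiling

    # ------------------------------------------------------------------ fit
    def fit(self, stack, y=None) -> "ZCalibration":
        """Fit the calibration from a bead-stack localization table.

        ``stack`` must provide columns ``width_x``, ``width_y`` and
        ``stage_z`` (known stage position per localization, nm) — either a
        :class:`LocalizationTable` or a bare DataFrame.
        """
        df = stack.df if isinstance(stack, LocalizationTable) else stack
        for col in ("width_x", "width_y", "stage_z"):
            if col not in df.columns:
                raise DataError(f"calibration stack lacks column {col!r}")
        sub = df[["stage_z", "width_x", "width_y"]].dropna()
        if len(sub) < 50:
            raise DataError(f"calibration needs >= 50 localizations with "
                            f"widths, got {len(sub)}")
        z = sub["stage_z"].to_numpy(dtype=float)
        span = z.max() - z.min()
        if span < 1000.0:
            raise DataError(f"calibration sweep must span >= 1 um, got "
                            f"{span:.0f} nm")
        # average widths in stage-z bins so the spline sees one strictly
        # increasing abscissa
        edges = np.arange(z.min(), z.max() + self.bin_width, self.bin_width)
        idx = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)
        order = np.argsort(idx, kind="stable")
        grouped = pd.DataFrame({
            "bin": idx, "wx": sub["width_x"].to_numpy(),
            "wy": sub["width_y"].to_numpy()}).groupby("bin").mean()
        zc = edges[grouped.index.to_numpy()] + self.bin_width / 2.0
        del order
        if len(zc) < 8:
            raise DataError("too few distinct stage-z bins for a spline fit")
        self.wx_spline_ = make_smoothing_spline(zc, grouped["wx"].to_numpy(),
                                                lam=self.smoothing)
        self.wy_spline_ = make_smoothing_spline(zc, grouped["wy"].to_numpy(),
                                                lam=self.smoothing)
        self._establish_range(zc.min(), zc.max())
        return self

    def _establish_range(self, lo: float, hi: float) -> None:
        """Trim validity to the monotone-discriminant interval around the
        focal crossing and locate the focal plane."""
        zg = np.arange(lo, hi + self.grid_step, self.grid_step)
        d = self.wx_spline_(zg) - self.wy_spline_(zg)
        dd = np.diff(d)
        if np.all(np.abs(d) < 1e-9) or np.all(np.abs(dd) < 1e-12):
            raise CalibrationError("astigmatism not resolvable: width "
                                   "difference is flat over the sweep")
        sign = np.sign(dd)
        sign[sign == 0] = 1
        # contiguous runs of strictly monotone discriminant
        breaks = np.flatnonzero(np.diff(sign) != 0) + 1
        starts = np.concatenate(([0], breaks))
        stops = np.concatenate((breaks, [len(dd)]))
        best = None
        for a, b in zip(starts, stops):
            seg = d[a:b + 1]
            if seg[0] * seg[-1] < 0:  # contains the focal crossing
                if best is None or (b - a) > (best[1] - best[0]):
                    best = (a, b)
        if best is None:
            raise CalibrationError("astigmatism not resolvable: discriminant "
                                   "has no monotone interval crossing zero")
        a, b = best
        z_lo, z_hi = float(zg[a]), float(zg[b])
        self.focal_z_ = float(brentq(
            lambda t: self.wx_spline_(t) - self.wy_spline_(t), z_lo, z_hi))
        self.z_range_ = (z_lo, z_hi)
        self.z_grid_ = np.arange(z_lo, z_hi + self.grid_step, self.grid_step)
        self.wx_grid_ = self.wx_spline_(self.z_grid_)
        self.wy_grid_ = self.wy_spline_(self.z_grid_)
        if np.any(self.wx_grid_ <= 0) or np.any(self.wy_grid_ <= 0):
            raise CalibrationError("calibrated width curves are not positive")

    # -------------------------------------------------------------- lookup
    def predict(self, width_x, width_y=None):
        """Axial offsets for fitted width pairs.

        Accepts either two arrays or a single ``(n, 2)`` array / DataFrame
        with ``width_x``/``width_y`` columns.  Returns a DataFrame with
        columns ``z`` (nm relative to the focal plane), ``residual``
        (width-space distance, nm) and ``rejected``.
        """
        if width_y is None:
            if isinstance(width_x, pd.DataFrame):
                wx = width_x["width_x"].to_numpy(dtype=float)
                wy = width_x["width_y"].to_numpy(dtype=float)
            else:
                arr = np.asarray(width_x, dtype=float)
                wx, wy = arr[:, 0], arr[:, 1]
        else:
            wx = np.atleast_1d(np.asarray(width_x, dtype=float))
            wy = np.atleast_1d(np.asarray(width_y, dtype=float))
        if np.any(wx <= 0) or np.any(wy <= 0):
            raise ParameterError("widths must be > 0")
        self._check_fitted()
        n = len(wx)
        z_out = np.empty(n)
        res_out = np.empty(n)
        step = self.grid_step
        for lo in range(0, n, 4096):
            hi = min(lo + 4096, n)
            cost = ((self.wx_grid_[None, :] - wx[lo:hi, None]) ** 2
                    + (self.wy_grid_[None, :] - wy[lo:hi, None]) ** 2)
            j = np.argmin(cost, axis=1)
            rows = np.arange(hi - lo)
            zb = self.z_grid_[j]
            # parabolic refinement where the minimum is interior
            interior = (j > 0) & (j < len(self.z_grid_) - 1)
            jm = np.clip(j - 1, 0, None)
            jp = np.clip(j + 1, None, len(self.z_grid_) - 1)
            c0, c1, c2 = cost[rows, jm], cost[rows, j], cost[rows, jp]
            denom = c0 - 2 * c1 + c2
            with np.errstate(divide="ignore", invalid="ignore"):
                off = np.where(interior & (denom > 0),
                               0.5 * (c0 - c2) / denom, 0.0)
            zb = zb + np.clip(off, -1, 1) * step
            res = np.sqrt((self.wx_spline_(zb) - wx[lo:hi]) ** 2
                          + (self.wy_spline_(zb) - wy[lo:hi]) ** 2)
            z_out[lo:hi] = zb
            res_out[lo:hi] = res
        return pd.DataFrame({
            "z": z_out - self.focal_z_,
            "residual": res_out,
            "rejected": res_out > self.rejection_ceiling,
        })

    def _check_fitted(self) -> None:
        if not hasattr(self, "wx_spline_"):
            raise CalibrationError("calibration is not fitted")

    # ------------------------------------------------------------- storage
    def save(self, csv_path, json_path=None) -> None:
        """Serialize as CSV (z_nm, wx_nm, wy_nm) plus a JSON sidecar."""
        self._check_fitted()
        csv_path = Path(csv_path)
        pd.DataFrame({"z_nm": self.z_grid_, "wx_nm": self.wx_grid_,
                      "wy_nm": self.wy_grid_}).to_csv(csv_path, index=False)
        side = Path(json_path) if json_path else csv_path.with_suffix(".json")
        side.write_text(json.dumps({
            "z_range": list(self.z_range_), "focal_z": self.focal_z_,
            "smoothing": self.smoothing, "grid_step": self.grid_step,
            "rejection_ceiling": self.rejection_ceiling}, indent=2))

    @classmethod
    def load(cls, csv_path, json_path=None) -> "ZCalibration":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        side = Path(json_path) if json_path else csv_path.with_suffix(".json")
        meta = json.loads(side.read_text())
        self = cls(smoothing=meta.get("smoothing"),
                   grid_step=meta.get("grid_step", 1.0),
                   rejection_ceiling=meta.get("rejection_ceiling",
                                              DEFAULT_REJECTION_CEILING))
        z = df["z_nm"].to_numpy()
        self.wx_spline_ = make_interp_spline(z, df["wx_nm"].to_numpy(), k=3)
        self.wy_spline_ = make_interp_spline(z, df["wy_nm"].to_numpy(), k=3)
        self.z_range_ = tuple(meta["z_range"])
        self.focal_z_ = float(meta["focal_z"])
        self.z_grid_ = z
        self.wx_grid_ = df["wx_nm"].to_numpy()
        self.wy_grid_ = df["wy_nm"].to_numpy()
        return self


def fit_calibration(stack, smoothing: float | None = None,
                    **kwargs) -> ZCalibration:
    """Fit a :class:`ZCalibration` from a bead stack (thin wrapper)."""
    return ZCalibration(smoothing=smoothing, **kwargs).fit(stack)


def lookup_z(width_x, width_y, calib: ZCalibration) -> pd.DataFrame:
    """Axial lookup for width pairs against a fitted calibration."""
    return calib.predict(width_x, width_y)
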