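"""Fiducial-based drift estimation, correction and round alignment.

Bright fluorescent beads adsorbed on the coverslip are imaged before and
after each measurement.  Averaging their localizations gives precise
anchor positions; matching the "pre" and "post" sets yields a rigid
transform whose translation (and optionally in-plane rotation) is the
accumulated drift.  Because the beads are recorded only at the two ends
of the acquisition, drift is interpolated linearly in acquisition time —
no higher-order model is identifiable from this design, and any
non-linear drift component shows up as residual (e.g. an instantaneous
jump at mid-acquisition leaves half its amplitude uncorrected at the
discontinuity).

The same machinery aligns sequential staining rounds: beads of the
second round are matched against the reference round and the estimated
transform (translation + optional rotation + optional uniform scale)
maps all round-2 localizations into the round-1 frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN

from .errors import FiducialError, ParameterError
from .scan import ScanSpec, global_time_fraction
from .table import LocalizationTable

MIN_LOCS_PER_BEAD = 10
MIN_MATCHED_PAIRS = 3


@dataclass
class FiducialSet:
    """Per-bead mean positions from one bead recording epoch."""

    positions: np.ndarray          # (n_beads, 3) nm
    spreads: np.ndarray            # (n_beads,) nm, rms positional std
    n_locs: np.ndarray             # (n_beads,) localizations averaged
    timestamp: str = "pre"

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class RigidTransform:
    """Similarity transform ``p -> center + scale * R(angle) (p - center)
    + translation`` with in-plane (xy) rotation.

    ``interpolated(t)`` scales the transform to a fraction of the
    acquisition, which is how linear-in-time drift is applied.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: float = 0.0
    scale: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rms_residual: float = 0.0
    n_pairs: int = 0

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s, 0.0], [s, c, 0.0],
                                      [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.center) @ self.matrix().T + self.center \
            + self.translation

    def inverse(self) -> "RigidTransform":
        inv_rot = -self.rotation
        inv_scale = 1.0 / self.scale
        c, s = np.cos(inv_rot), np.sin(inv_rot)
        r_inv = inv_scale * np.array([[c, -s, 0.0], [s, c, 0.0],
                                      [0.0, 0.0, 1.0]])
        return RigidTransform(translation=-(r_inv @ self.translation),
                              rotation=inv_rot, scale=inv_scale,
                              center=self.center.copy(),
                              rms_residual=self.rms_residual,
                              n_pairs=self.n_pairs)

    def interpolated(self, t: float) -> "RigidTransform":
        return RigidTransform(translation=self.translation * t,
                              rotation=self.rotation * t,
                              scale=self.scale ** t,
                              center=self.center.copy())


def _positions(beads) -> np.ndarray:
    if isinstance(beads, FiducialSet):
        return beads.positions
    return np.asarray(beads, dtype=float)


def summarize_beads(bead_table: LocalizationTable,
                    merge_radius: float = 100.0,
                    timestamp: str = "pre") -> FiducialSet:
    """Collapse raw bead localizations into one mean position per bead.

    Localizations within ``merge_radius`` of each other (single linkage)
    belong to one bead; beads averaged from fewer than 10 localizations
    are discarded as unreliable anchors.
    """
    if len(bead_table) == 0:
        raise FiducialError("bead table is empty")
    df = bead_table.df
    cols = ["x", "y", "z"] if bead_table.has_z else ["x", "y"]
    pts = df[cols].to_numpy(dtype=float)
    # DBSCAN with min_samples=1 is exactly the single-linkage cut at eps
    labels = DBSCAN(eps=merge_radius, min_samples=1).fit_predict(pts)
    positions, spreads, counts = [], [], []
    for lab in np.unique(labels):
        member = pts[labels == lab]
        if len(member) < MIN_LOCS_PER_BEAD:
            continue
        mean = member.mean(axis=0)
        if len(cols) == 2:
            mean = np.append(mean, 0.0)
        positions.append(mean)
        spreads.append(float(np.sqrt(member.var(axis=0).mean())))
        counts.append(len(member))
    if not positions:
        raise FiducialError("no bead had the minimum of "
                            f"{MIN_LOCS_PER_BEAD} localizations")
    return FiducialSet(positions=np.array(positions),
                       spreads=np.array(spreads),
                       n_locs=np.array(counts), timestamp=timestamp)


def _mutual_matches(a: np.ndarray, b: np.ndarray,
                    max_dist: float) -> tuple[np.ndarray, np.ndarray]:
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a, distance_upper_bound=max_dist)
    d_ba, j_ba = ta.query(b, distance_upper_bound=max_dist)
    ia = np.arange(len(a))
    ok = np.isfinite(d_ab) & (j_ab < len(b))
    mutual = ok & (j_ba[np.clip(j_ab, 0, len(b) - 1)] == ia)
    return ia[mutual], j_ab[mutual]


def estimate_transform(pre, post, max_match_dist: float = 500.0,
                       allow_rotation: bool = False,
                       allow_scale: bool = False) -> RigidTransform:
    """Least-squares transform mapping ``pre`` bead positions onto ``post``.

    Beads are paired by mutual nearest neighbour within
    ``max_match_dist``.  The translation is the least-squares optimum;
    with ``allow_rotation`` the in-plane rotation is solved by orthogonal
    Procrustes on the matched pairs, with ``allow_scale`` a uniform scale
    is added (used for round alignment, not drift).
    """
    a, b = _positions(pre), _positions(post)
    if len(a) == 0 or len(b) == 0:
        raise FiducialError("empty fiducial set")
    ia, ib = _mutual_matches(a, b, max_match_dist)
    if len(ia) >= MIN_MATCHED_PAIRS:
        # second pass: pre-align by the (robust) median displacement and
        # rematch, so one crossed pairing among close-by beads cannot
        # drag the least-squares translation
        t0 = np.median(b[ib] - a[ia], axis=0)
        ia, ib = _mutual_matches(a + t0, b, max_match_dist)
    if len(ia) < MIN_MATCHED_PAIRS:
        raise FiducialError(
            f"only {len(ia)} fiducial pairs matched within "
            f"{max_match_dist:.0f} nm; need >= {MIN_MATCHED_PAIRS}")
    pa, pb = a[ia], b[ib]
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    angle, scale = 0.0, 1.0
    if allow_rotation:
        h = (pa[:, :2] - ca[:2]).T @ (pb[:, :2] - cb[:2])
        u, _, vt = np.linalg.svd(h)
        r2 = vt.T @ u.T
        if np.linalg.det(r2) < 0:          # keep a proper rotation
            vt[-1] *= -1
            r2 = vt.T @ u.T
        angle = float(np.arctan2(r2[1, 0], r2[0, 0]))
    tf = RigidTransform(rotation=angle, center=ca.copy())
    if allow_scale:
        rot = tf.matrix()
        ra = (pa - ca) @ rot.T
        denom = float(np.sum(ra * ra))
        if denom > 0:
            scale = float(np.sum(ra * (pb - cb)) / denom)
    tf.scale = scale
    tf.translation = cb - ca
    resid = tf.apply(pa) - pb
    tf.rms_residual = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    tf.n_pairs = int(len(ia))
    return tf


def correct_drift(table: LocalizationTable, transform: RigidTransform,
                  spec: ScanSpec) -> LocalizationTable:
    """Undo linear-in-time drift described by ``transform``.

    Each record is moved by the inverse of the transform scaled to its
    global time fraction across the acquisition (computed from movie_id
    and frame).  Record order and count are untouched.
    """
    df = table.df
    for col in ("frame", "movie_id"):
        if col not in df.columns:
            raise ParameterError(f"drift correction needs column {col!r}")
    if not table.has_z:
        raise ParameterError("drift correction expects an assembled table "
                             "with z")
    t = global_time_fraction(df["frame"].to_numpy(),
                             df["movie_id"].to_numpy(), spec)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    out = pts.copy()
    # piecewise application: group records into narrow time bins so the
    # per-record interpolated transform stays exact for pure translations
    # and accurate to < 1e-3 deg for realistic rotations
    if transform.rotation == 0.0 and transform.scale == 1.0:
        out = pts - t[:, None] * transform.translation[None, :]
    else:
        order = np.argsort(t, kind="stable")
        bins = np.clip((t * 4096).astype(int), 0, 4095)
        for b in np.unique(bins):
            sel = bins == b
            tf = transform.interpolated(float(t[sel].mean())).inverse()
            out[sel] = tf.apply(pts[sel])
        del order
    new = df.copy()
    new[["x", "y", "z"]] = out
    return table.replace(new, drift_corrected=True,
                         drift_translation=transform.translation.tolist(),
                         drift_rms_residual=transform.rms_residual)


def align_rounds(round2: LocalizationTable, pre2, reference,
                 allow_rotation: bool = False,
                 allow_scale: bool = False,
                 max_match_dist: float = 500.0) -> LocalizationTable:
    """Map round-2 localizations into the round-1 coordinate frame.

    ``pre2`` holds the coverslip beads as seen by round 2, ``reference``
    the same physical beads in the round-1 frame.
    """
    tf = estimate_transform(pre2, reference, max_match_dist=max_match_dist,
                            allow_rotation=allow_rotation,
                            allow_scale=allow_scale)
    df = round2.df.copy()
    cols = ["x", "y", "z"] if round2.has_z else ["x", "y"]
    pts = df[cols].to_numpy(dtype=float)
    if len(cols) == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    moved = tf.apply(pts)
    df[cols] = moved[:, :len(cols)]
    return round2.replace(df, aligned_to="reference",
                          alignment_residual=tf.rms_residual,
                          alignment_pairs=tf.n_pairs)


class DriftCorrector(BaseEstimator):
    """Estimator wrapper: fit on pre/post fiducials, transform tables.

    Parameters mirror :func:`estimate_transform`; ``spec`` supplies the
    frame-to-time mapping used for linear interpolation.
    """

    def __init__(self, spec: ScanSpec | None = None,
                 max_match_dist: float = 500.0,
                 allow_rotation: bool = False,
                 merge_radius: float = 100.0):
        self.spec = spec
        self.max_match_dist = max_match_dist
        self.allow_rotation = allow_rotation
        self.merge_radius = merge_radius

    def fit(self, pre, post=None) -> "DriftCorrector":
        """``pre``/``post``: FiducialSet, position array, or raw bead
        LocalizationTable (summarized automatically)."""
        if post is None:
            pre, post = pre
        pre = self._as_fiducials(pre, "pre")
        post = self._as_fiducials(post, "post")
        self.transform_ = estimate_transform(
            pre, post, max_match_dist=self.max_match_dist,
            allow_rotation=self.allow_rotation)
        return self

    def _as_fiducials(self, obj, stamp):
        if isinstance(obj, LocalizationTable):
            return summarize_beads(obj, merge_radius=self.merge_radius,
                                   timestamp=stamp)
        return obj

    def transform(self, table: LocalizationTable) -> LocalizationTable:
        if not hasattr(self, "transform_"):
            raise FiducialError("DriftCorrector is not fitted")
        if self.spec is None:
            raise ParameterError("DriftCorrector needs a ScanSpec to map "
                                 "frames to acquisition time")
        return correct_drift(table, self.transform_, self.spec)
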