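"""Denoising, cluster segmentation, metrics, truncation and reduction
robustness analysis for volumetric localization point clouds.

The segmentation pipeline mirrors the study design: DBSCAN removes
isolated noise localizations, a Gaussian density map is thresholded and
its 26-connected components become protein clusters, and every cluster
is quantified by its localization count (blinking events, a proxy for
relative protein content), 3D Feret length (maximum pairwise member
distance — reproducible and rotation-invariant where 2D measurements
used a freehand line), width along the second principal axis, isosurface
volume and count density.  Clusters with fewer than eight localizations
are discarded — artifacts of one or two blinking events survive any
density threshold because a single deposit peaks far above typical
background levels.

The reduction experiment probes labeling-efficiency robustness: the
table is deterministically thinned to 90/80/66/50/33/20/10% by omitting
or keeping every n-th localization, the density threshold is scaled
proportionally to the thinning, a 160 nm length floor removes
single-localization artifacts, and a Kruskal-Wallis test asks whether
cluster length shifted across reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kruskal
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .density import (Grid, auto_iso_threshold, sparse_isosurface,
                      NM3_PER_UM3)
from .errors import ParameterError
from .table import LocalizationTable

#: Deterministic thinning schemes: (keep_mode, n) where omit drops every
#: n-th localization (0-based index n-1 mod n) and keep retains every
#: n-th (index 0 mod n).
SUBSAMPLE_SCHEMES = {
    1.0: None,
    0.9: ("omit", 10),
    0.8: ("omit", 5),
    0.66: ("omit", 3),
    0.5: ("omit", 2),
    0.33: ("keep", 3),
    0.2: ("keep", 5),
    0.1: ("keep", 10),
}

REDUCTION_MIN_LENGTH = 160.0   # nm, floor for reduced-data runs


@dataclass
class ClusterParams:
    """Tunable parameters of denoising and segmentation (lengths in nm)."""

    dbscan_eps: float = 100.0
    dbscan_min_pts: int = 8
    voxel_size: float = 20.0
    kernel_sigma: tuple = (30.0, 30.0, 60.0)   # x, y lateral; z axial
    iso_threshold: float | None = None          # per um^3; None -> auto
    min_count: int = 8
    min_length: float = 0.0
    border_margin: float | None = None          # default: one voxel

    def __post_init__(self) -> None:
        for name in ("dbscan_eps", "dbscan_min_pts", "voxel_size",
                     "min_count"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.min_length < 0:
            raise ParameterError("min_length must be >= 0")
        if self.iso_threshold is not None and self.iso_threshold <= 0:
            raise ParameterError("iso_threshold must be > 0 when given")

    @property
    def margin(self) -> float:
        return self.border_margin if self.border_margin is not None \
            else self.voxel_size


@dataclass
class Cluster:
    """One segmented protein cluster and its metrics."""

    cluster_id: int
    member_ids: np.ndarray          # row indices into the segmented table
    count: int
    centroid: np.ndarray            # (3,) nm
    length: float                   # nm, 3D Feret diameter of the members
    width: float                    # nm, extent along 2nd principal axis
    volume: float                   # um^3, isosurface voxel volume
    density: float                  # counts per um^3 (= count / volume)
    mask_length: float = 0.0        # nm, Feret diameter of the voxel mask
    bounds_min: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bounds_max: np.ndarray = field(default_factory=lambda: np.zeros(3))
    truncated: bool = False
    bouton_id: int | None = None


@dataclass
class SegmentationResult:
    """Clusters plus the bookkeeping needed for count conservation:
    ``sum(cluster counts) + n_unassigned + n_dropped_locs`` equals the
    number of input localizations."""

    clusters: list
    n_input: int
    n_unassigned: int
    n_dropped_clusters: int
    n_dropped_locs: int
    iso_threshold: float
    grid: Grid

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "cluster_id": c.cluster_id, "count": c.count,
            "centroid_x_nm": c.centroid[0], "centroid_y_nm": c.centroid[1],
            "centroid_z_nm": c.centroid[2], "length_nm": c.length,
            "mask_length_nm": c.mask_length,
            "width_nm": c.width, "volume_um3": c.volume,
            "density_per_um3": c.density, "truncated": c.truncated,
            "bouton_id": c.bouton_id if c.bouton_id is not None else -1,
        } for c in self.clusters]
        return pd.DataFrame(rows)


def denoise(table: LocalizationTable, eps: float = 100.0,
            min_pts: int = 8) -> LocalizationTable:
    """Remove DBSCAN noise points (label -1) from the 3D point cloud."""
    if len(table) == 0:
        return table.replace(table.df, denoise_removed=0)
    if not table.has_z:
        raise ParameterError("denoise needs z")
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        table.coords("xyz"))
    keep = labels != -1
    return table.replace(table.df.loc[keep],
                         denoise_removed=int((~keep).sum()),
                         denoise_eps=eps, denoise_min_pts=min_pts)


def _feret(points: np.ndarray) -> float:
    """Maximum pairwise distance (3D Feret diameter)."""
    n = len(points)
    if n < 2:
        return 0.0
    if n > 60:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) — brute force below
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _width(points: np.ndarray) -> float:
    """Extent along the second principal axis of the members."""
    if len(points) < 3:
        return 0.0
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[1]
    return float(proj.max() - proj.min())


def _metrics(members: np.ndarray, idx: np.ndarray, n_vox: int,
             vox_vol: float, cid: int) -> Cluster:
    count = len(members)
    volume = n_vox * vox_vol
    length = _feret(members)
    width = _width(members)
    return Cluster(cluster_id=cid, member_ids=idx, count=count,
                   centroid=members.mean(axis=0), length=length,
                   width=min(width, length), volume=volume,
                   density=count / volume,
                   bounds_min=members.min(axis=0),
                   bounds_max=members.max(axis=0))


def segment_clusters(table: LocalizationTable, params: ClusterParams,
                     method: str = "isosurface") -> SegmentationResult:
    """Segment protein clusters from a (denoised) volumetric table.

    ``method='isosurface'`` (default) thresholds the Gaussian density map
    at ``params.iso_threshold`` (auto-estimated when None) and labels
    26-connected components; every localization is assigned to the
    component containing its voxel.  ``method='dbscan'`` is an
    alternative segmentation by DBSCAN itself, provided for sensitivity
    analysis (cluster volume then comes from the member convex hull).

    Clusters below ``min_count`` localizations or shorter than
    ``min_length`` are dropped; the result records how many localizations
    left through each route so that the totals balance exactly.
    """
    if not table.has_z:
        raise ParameterError("segmentation needs z")
    pts = table.coords("xyz")
    n_input = len(pts)
    if n_input == 0:
        return SegmentationResult([], 0, 0, 0, 0,
                                  params.iso_threshold or 0.0,
                                  Grid((0, 0, 0), params.voxel_size,
                                       (1, 1, 1)))
    if method == "isosurface":
        iso = params.iso_threshold
        if iso is None:
            iso = auto_iso_threshold(pts)
        labels, vox_keys, vox_labels, grid = sparse_isosurface(
            pts, params.voxel_size, params.kernel_sigma, iso)
        vox_counts = np.bincount(vox_labels,
                                 minlength=int(vox_labels.max(initial=0)) + 1)
        vox_order = np.argsort(vox_labels, kind="stable")
        vox_starts = np.searchsorted(
            vox_labels[vox_order],
            np.arange(1, int(vox_labels.max(initial=0)) + 2))
        vox_idx = grid.unkey(vox_keys)
    elif method == "dbscan":
        iso = 0.0
        grid = Grid(tuple(pts.min(axis=0)), params.voxel_size,
                    (1, 1, 1))
        raw = DBSCAN(eps=params.dbscan_eps,
                     min_samples=params.dbscan_min_pts).fit_predict(pts)
        labels = raw + 1            # 0 = noise/unassigned
        vox_counts = None
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")

    n_unassigned = int((labels == 0).sum())
    clusters: list[Cluster] = []
    n_dropped_clusters = 0
    n_dropped_locs = 0
    vox_vol = grid.voxel_volume_um3
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    starts = np.searchsorted(sorted_labels, np.arange(1, labels.max(initial=0) + 2))
    for lab in range(1, labels.max(initial=0) + 1):
        idx = order[starts[lab - 1]:starts[lab]]
        if len(idx) == 0:
            continue
        members = pts[idx]
        if vox_counts is not None:
            n_vox = int(vox_counts[lab])
            volume_refs = (n_vox, vox_vol)
        else:
            try:
                hull_vol = ConvexHull(members).volume / NM3_PER_UM3
            except QhullError:
                hull_vol = vox_vol
            volume_refs = (1, max(hull_vol, vox_vol))
        c = _metrics(members, idx, *volume_refs, cid=-1)
        if vox_counts is not None:
            sel = vox_order[vox_starts[lab - 1]:vox_starts[lab]]
            c.mask_length = _feret(grid.voxel_centers(vox_idx[sel]))
        else:
            c.mask_length = c.length
        # the length floor addresses isosurface artifacts, so it tests the
        # object's own extent (mask length) where a mask exists
        size_length = c.mask_length if vox_counts is not None else c.length
        if c.count < params.min_count or size_length < params.min_length:
            n_dropped_clusters += 1
            n_dropped_locs += c.count
            continue
        clusters.append(c)
    # deterministic ids by centroid lexicographic order
    clusters.sort(key=lambda c: tuple(c.centroid))
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return SegmentationResult(clusters=clusters, n_input=n_input,
                              n_unassigned=n_unassigned,
                              n_dropped_clusters=n_dropped_clusters,
                              n_dropped_locs=n_dropped_locs,
                              iso_threshold=float(iso), grid=grid)


class DensitySegmenter(ClusterMixin, BaseEstimator):
    """sklearn-style clusterer over 3D localization coordinates.

    ``fit_predict(X)`` on an ``(n, 3)`` coordinate array (nm) returns
    per-point labels: 0..k-1 for cluster members, -1 for unassigned or
    dropped points.  Fitted attributes expose the full result
    (``clusters_``, ``result_``).
    """

    def __init__(self, voxel_size: float = 20.0,
                 kernel_sigma=(30.0, 30.0, 60.0),
                 iso_threshold: float | None = None, min_count: int = 8,
                 min_length: float = 0.0, method: str = "isosurface",
                 dbscan_eps: float = 100.0, dbscan_min_pts: int = 8):
        self.voxel_size = voxel_size
        self.kernel_sigma = kernel_sigma
        self.iso_threshold = iso_threshold
        self.min_count = min_count
        self.min_length = min_length
        self.method = method
        self.dbscan_eps = dbscan_eps
        self.dbscan_min_pts = dbscan_min_pts

    def fit(self, X, y=None) -> "DensitySegmenter":
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame({"x": X[:, 0], "y": X[:, 1], "z": X[:, 2],
                           "frame": 0})
        table = LocalizationTable(df=df)
        params = ClusterParams(voxel_size=self.voxel_size,
                               kernel_sigma=tuple(np.atleast_1d(
                                   self.kernel_sigma)),
                               iso_threshold=self.iso_threshold,
                               min_count=self.min_count,
                               min_length=self.min_length,
                               dbscan_eps=self.dbscan_eps,
                               dbscan_min_pts=self.dbscan_min_pts)
        self.result_ = segment_clusters(table, params, method=self.method)
        self.clusters_ = self.result_.clusters
        labels = np.full(len(X), -1, dtype=np.int64)
        for c in self.clusters_:
            labels[c.member_ids] = c.cluster_id
        self.labels_ = labels
        return self


def flag_truncation(clusters: list, roi, margin: float = 20.0,
                    axes=("z",)) -> list:
    """Mark clusters whose members reach within ``margin`` of an ROI face.

    ``roi`` is a mapping axis -> (lo, hi) in nm or a 3-tuple of (lo, hi)
    pairs for (x, y, z).  Only the listed axes are checked; z by default,
    because axial truncation at the scan borders is the bias the
    volumetric protocol is designed to remove.  Clusters are annotated in
    place and returned.
    """
    if not isinstance(roi, dict):
        roi = dict(zip("xyz", roi))
    ax_idx = {"x": 0, "y": 1, "z": 2}
    for c in clusters:
        t = False
        for a in axes:
            lo, hi = roi[a]
            i = ax_idx[a]
            if c.bounds_min[i] < lo + margin or c.bounds_max[i] > hi - margin:
                t = True
        c.truncated = t
    return clusters


def subsample(table: LocalizationTable, fraction: float) -> LocalizationTable:
    """Deterministic thinning to one of the supported fractions.

    Reductions above half omit every n-th localization (0-based indices
    ``n-1 mod n``); reductions at or below a third keep every n-th
    (indices ``0 mod n``).  The operation is order-preserving and
    idempotent in the sense that it depends only on record order.
    """
    if fraction not in SUBSAMPLE_SCHEMES:
        raise ParameterError(
            f"unsupported fraction {fraction}; choose from "
            f"{sorted(SUBSAMPLE_SCHEMES)}")
    scheme = SUBSAMPLE_SCHEMES[fraction]
    if scheme is None:
        return table.replace(table.df, subsample_fraction=1.0)
    mode, n = scheme
    idx = np.arange(len(table))
    keep = (idx % n != n - 1) if mode == "omit" else (idx % n == 0)
    return table.replace(table.df.iloc[keep],
                         subsample_fraction=fraction,
                         subsample_scheme=f"{mode} every {n}th")


@dataclass
class ReductionResult:
    """Per-fraction length distributions and the omnibus test."""

    lengths: dict                    # fraction -> np.ndarray of nm lengths
    n_clusters: dict                 # fraction -> int
    kruskal_h: float
    kruskal_p: float
    iso_threshold: float             # threshold at fraction 1.0


def reduction_experiment(table: LocalizationTable, params: ClusterParams,
                         fractions=(1.0, 0.9, 0.8, 0.66, 0.5, 0.33, 0.2, 0.1),
                         ) -> ReductionResult:
    """Segment at each reduced density with a proportionally scaled
    threshold and the 160 nm length floor; test length stability."""
    pts = table.coords("xyz")
    base_iso = params.iso_threshold
    if base_iso is None:
        base_iso = auto_iso_threshold(pts)
    lengths, n_clusters = {}, {}
    for f in fractions:
        sub = subsample(table, f)
        p = dc_replace(params, iso_threshold=base_iso * f,
                       min_length=max(params.min_length,
                                      REDUCTION_MIN_LENGTH))
        res = segment_clusters(sub, p)
        # the stability claim concerns the reconstructed object's extent:
        # the isosurface boundary is invariant under proportional threshold
        # scaling in expectation, whereas the members' own Feret shrinks
        # with every thinning simply because extremes are sampled less
        lengths[f] = np.array([c.mask_length for c in res.clusters])
        n_clusters[f] = len(res.clusters)
    groups = [lengths[f] for f in fractions if len(lengths[f]) > 0]
    if len(groups) >= 2 and not all(
            np.array_equal(groups[0], g) for g in groups[1:]):
        h, p_val = kruskal(*groups)
    elif len(groups) >= 2:
        h, p_val = 0.0, 1.0      # identical groups: no evidence of shift
    else:
        h, p_val = float("nan"), float("nan")
    return ReductionResult(lengths=lengths, n_clusters=n_clusters,
                           kruskal_h=float(h), kruskal_p=float(p_val),
                           iso_threshold=base_iso)


def depth_profile(table: LocalizationTable, n_bins: int = 10) -> pd.DataFrame:
    """Per-z-bin medians of intensity, intensity/background and counts.

    A depth-homogeneous profile is the quality check that the imaging
    volume is free of serious spherical aberration.
    """
    for col in ("z", "intensity", "background"):
        if col not in table.df.columns:
            raise ParameterError(f"depth profile needs column {col!r}")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    z = table.df["z"].to_numpy(dtype=float)
    edges = np.linspace(z.min(), z.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        sub = table.df.loc[sel]
        inten = sub["intensity"].to_numpy(dtype=float)
        bg = sub["background"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(bg > 0, inten / bg, np.nan)
        rows.append({
            "z_center_nm": 0.5 * (edges[b] + edges[b + 1]),
            "median_intensity": float(np.median(inten)) if sel.any() else np.nan,
            "median_intensity_over_background":
                float(np.nanmedian(ratio)) if sel.any() else np.nan,
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)
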