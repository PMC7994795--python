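"""Bouton surface reconstruction and cluster-to-bouton assignment.

The second staining round labels the presynaptic membrane (membrane-bound
EGFP read out with anti-GFP nanobodies), so each mossy-fiber bouton
appears as a hollow shell of localizations.  Reconstruction thresholds
the membrane density map, morphologically closes the shell to bridge
labeling gaps, fills it, and takes 26-connected components above a
minimum volume as candidate boutons.  The study separated boutons from
their supporting axons manually; here that step is mirrored by optional
seed points — when given, candidate voxels are split by nearest-seed
assignment, the only user-in-the-loop input of the pipeline.

A protein cluster belongs to a bouton when its centroid lies inside the
filled bouton mask (boundary voxels count as inside, so centroids on the
surface are assigned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .clusters import Cluster, ClusterParams
from .density import Grid, auto_iso_threshold, render_density_3d
from .errors import ParameterError
from .stats import spearman_correlation
from .table import LocalizationTable

DEFAULT_CLOSING_RADIUS = 3      # voxels


@dataclass
class BoutonSurface:
    """Filled voxel mask and summary of one reconstructed bouton."""

    bouton_id: int
    voxel_keys: np.ndarray          # sorted flat keys into ``grid``
    grid: Grid
    volume: float                   # um^3 (= len(voxel_keys) * voxel vol)
    centroid: np.ndarray            # (3,) nm
    n_clusters: int = 0


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.indices((2 * r + 1,) * 3) - r
    return (np.sum(g ** 2, axis=0) <= r ** 2)


def reconstruct_boutons(membrane_table: LocalizationTable,
                        params: ClusterParams | None = None,
                        min_volume: float = 1.0,
                        seeds=None,
                        closing_radius: int = DEFAULT_CLOSING_RADIUS,
                        ) -> list[BoutonSurface]:
    """Reconstruct filled bouton masks from membrane-channel localizations.

    Parameters
    ----------
    membrane_table : LocalizationTable
        Second-round (membrane) localizations with z.
    params : ClusterParams
        Supplies voxel size, kernel sigma and iso threshold (auto when
        None).
    min_volume : float
        Minimum filled volume (um^3) for a component to count as a
        bouton candidate; smaller membrane fragments (axon pieces,
        debris) are ignored.
    seeds : DataFrame or (n, 3)/(n, 4) array, optional
        Seed points (``bouton_id, x_nm, y_nm, z_nm`` columns, or plain
        coordinates) marking individual boutons; candidate voxels are
        split by nearest seed, standing in for manual separation.
    """
    params = params or ClusterParams()
    if len(membrane_table) == 0:
        return []
    if not membrane_table.has_z:
        raise ParameterError("bouton reconstruction needs z")
    pts = membrane_table.coords("xyz")
    iso = params.iso_threshold
    if iso is None:
        # a membrane label paints surfaces, not compact volumes: its local
        # density sits near the scene mean, so the surface threshold is
        # gentler than the 5x-background default used for clusters
        iso = auto_iso_threshold(pts, factor=1.0)
    values, grid = render_density_3d(pts, params.voxel_size,
                                     params.kernel_sigma)
    band = values >= iso
    mask = band
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    # the filled region is bounded by the *outer* isosurface, which sits
    # roughly half a shell thickness outside the membrane midline; erode
    # back by the median depth of the raw density band, a self-calibrated
    # estimate of that offset, so volumes refer to the membrane midsurface
    depth = ndimage.distance_transform_edt(mask)
    inner = band & mask
    if inner.any():
        delta = float(np.median(depth[inner]))
        mask = depth >= delta
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n_lab == 0:
        return []
    vox_vol = grid.voxel_volume_um3
    counts = np.bincount(labels.ravel())
    keep = [lab for lab in range(1, n_lab + 1)
            if counts[lab] * vox_vol >= min_volume]
    if not keep:
        return []
    cand = np.isin(labels, keep)
    idx = np.argwhere(cand)
    centers = grid.voxel_centers(idx)
    if seeds is not None:
        seed_ids, seed_pts = _parse_seeds(seeds)
        d2 = np.sum((centers[:, None, :] - seed_pts[None, :, :]) ** 2,
                    axis=-1)
        owner = np.argmin(d2, axis=1)
        groups = [(int(seed_ids[s]), idx[owner == s])
                  for s in range(len(seed_pts))]
    else:
        groups = [(i, np.argwhere(labels == lab))
                  for i, lab in enumerate(keep)]
    out = []
    for bid, vox in groups:
        if len(vox) == 0:
            continue
        keys = np.sort(grid.keys(vox))
        out.append(BoutonSurface(
            bouton_id=bid, voxel_keys=keys, grid=grid,
            volume=len(keys) * vox_vol,
            centroid=grid.voxel_centers(vox).mean(axis=0)))
    out.sort(key=lambda b: b.bouton_id)
    return out


def _parse_seeds(seeds):
    if isinstance(seeds, pd.DataFrame):
        ids = seeds["bouton_id"].to_numpy()
        pts = seeds[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(seeds, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (3, 4):
            raise ParameterError("seeds must be (n, 3) coordinates or "
                                 "(n, 4) with a leading bouton_id")
        if arr.shape[1] == 4:
            ids, pts = arr[:, 0].astype(int), arr[:, 1:]
        else:
            ids, pts = np.arange(len(arr)), arr
    return ids, pts


def assign_clusters(clusters: list[Cluster],
                    boutons: list[BoutonSurface]) -> list[Cluster]:
    """Assign each cluster to the bouton whose filled mask contains its
    centroid voxel; clusters outside every mask stay unassigned.

    Masks are disjoint by construction, so assignment is deterministic;
    boundary voxels belong to their bouton (inclusive convention).
    """
    for b in boutons:
        b.n_clusters = 0
    for c in clusters:
        c.bouton_id = None
        for b in boutons:
            idx = b.grid.indices(c.centroid[None, :])
            if not b.grid.inside(idx)[0]:
                continue
            key = b.grid.keys(idx)[0]
            pos = np.searchsorted(b.voxel_keys, key)
            if pos < len(b.voxel_keys) and b.voxel_keys[pos] == key:
                c.bouton_id = b.bouton_id
                b.n_clusters += 1
                break
    return clusters


def per_bouton_summary(clusters: list[Cluster],
                       boutons: list[BoutonSurface]):
    """Per-bouton table plus the volume-vs-cluster-number correlation.

    Returns ``(table, spearman)`` where ``spearman`` is ``(r, p)`` over
    (bouton volume, assigned cluster count) or ``None`` with fewer than
    three boutons (a correlation over two points is meaningless).
    """
    rows = []
    for b in boutons:
        mine = [c for c in clusters if c.bouton_id == b.bouton_id]
        rows.append({
            "bouton_id": b.bouton_id,
            "volume_um3": b.volume,
            "n_clusters": len(mine),
            "median_count": float(np.median([c.count for c in mine]))
                if mine else np.nan,
            "median_length_nm": float(np.median([c.length for c in mine]))
                if mine else np.nan,
            "median_volume_um3": float(np.median([c.volume for c in mine]))
                if mine else np.nan,
            "centroid_x_nm": b.centroid[0],
            "centroid_y_nm": b.centroid[1],
            "centroid_z_nm": b.centroid[2],
        })
    df = pd.DataFrame(rows)
    corr = None
    if len(df) >= 3:
        corr = spearman_correlation(df["volume_um3"].to_numpy(),
                                    df["n_clusters"].to_numpy())
    return df, corr
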