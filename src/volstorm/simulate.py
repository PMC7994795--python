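"""Synthetic volumetric SMLM acquisitions with full ground truth.

The generator emulates the structure of a sequential en-bloc scanning
experiment: prolate-ellipsoidal protein clusters with lognormal lengths
scattered through a 25 x 25 x 10 um imaging window, per-cluster blinking
budgets drawn negative-binomially (mean 139, SD ~80 events per cluster,
matching measured per-cluster localization counts), uniform background
localizations, ~10 coverslip fiducial beads, a triangular piezo
trajectory with direction alternation, astigmatic PSF widths from a
standard defocus model, linear drift over the acquisition and geometric
per-scan photobleaching.  An emitter is detected only while the focal
plane is within the astigmatic capture half-range of its axial position.

Blinking is modeled as i.i.d. Poisson detections per emitter per
in-focus pass — enough to exercise counting and densities, not a
photophysics model.  Cluster geometry is a uniformly filled prolate
ellipsoid; the width/length anisotropy (aspect 0.2) echoes the measured
side-view cross sections (~74 nm width vs ~376 nm length).

The defocus model parameters (w0 = 150 nm, focal offsets +/-400 nm,
depth scale 500 nm) are simulator conventions; the spline calibration
downstream never assumes this functional form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .clusters import ClusterParams, _feret
from .errors import ParameterError
from .scan import ScanSpec, stage_z, global_time_fraction
from .table import LocalizationTable


@dataclass
class DefocusModel:
    """Astigmatic width model ``w(dz) = w0 sqrt(1 + ((dz -/+ c)/d)^2)``:
    width_x focuses ``c`` below, width_y ``c`` above the nominal plane,
    so their difference is monotone in defocus."""

    w0: float = 150.0      # in-focus PSF sigma (nm)
    c: float = 400.0       # astigmatic focal offset (nm)
    d: float = 500.0       # depth scale (nm)

    def widths(self, dz):
        dz = np.asarray(dz, dtype=float)
        wx = self.w0 * np.sqrt(1.0 + ((dz + self.c) / self.d) ** 2)
        wy = self.w0 * np.sqrt(1.0 + ((dz - self.c) / self.d) ** 2)
        return wx, wy


@dataclass
class SceneSpec:
    """Study-condition parameters of a simulated acquisition.

    Distances in the units noted; the defaults are the conditions the
    pipeline is validated under: a 25 x 25 um imaging window scanned
    over 10 um in ten alternating 15,000-frame movies, clusters with a
    450 nm median length and a mean blinking budget of 139 events.
    """

    field_of_view: tuple = (25.0, 25.0)        # um
    z_extent: float = 10.0                      # um
    n_clusters: int = 200
    cluster_length_median: float = 450.0        # nm
    cluster_length_sigma: float = 0.3           # lognormal sigma (log scale)
    cluster_aspect: float = 0.2                 # width / length
    locs_per_cluster_mean: float = 139.0        # NB mean blinking events
    locs_per_cluster_sd: float = 80.0           # NB standard deviation
    background_density: float = 0.5             # strays per um^3
    n_beads: int = 10
    bead_locs: int = 50
    bead_sigma: float = 3.0                     # nm per-localization spread
    precision: tuple = (15.0, 45.0)             # nm (lateral, axial) sigma
    width_noise: float = 5.0                    # nm PSF width noise
    drift: tuple = (30.0, -20.0, 15.0)          # nm over the acquisition
    bleach_per_scan: float = 0.05               # emitter loss per scan
    capture_halfwidth: float = 500.0            # nm astigmatic visibility
    blinks_per_pass: float = 0.5                # mean detections per pass
    truncation_fraction: float = 0.0            # clusters straddling z edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.background_density < 0:
            raise ParameterError("counts and densities must be >= 0")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ParameterError("truncation_fraction must be in [0, 1]")
        if self.cluster_length_median >= min(self.field_of_view) * 1000:
            raise ParameterError("clusters larger than the field of view")

    def scan_spec(self) -> ScanSpec:
        return ScanSpec(z_travel=self.z_extent)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SceneTruth:
    """Complete ground truth of one simulated scene.

    The cluster table carries both the envelope axis length (``length``,
    the lognormal draw that sized the ellipsoid) and the realized
    measurable length (``feret``, the maximum pairwise distance of the
    emitters actually placed): with finitely many emitters the extreme
    poles of the envelope carry almost no mass, so ``feret`` — not the
    envelope — is the ground truth a length-recovery comparison should
    use.
    """

    clusters: pd.DataFrame          # per-cluster geometry and counts
    beads: np.ndarray               # (n_beads, 3) true positions at t=0
    drift: np.ndarray               # (3,) nm over the acquisition
    spec: SceneSpec
    loc_labels: list = field(default_factory=list)  # per-movie cluster ids


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _sample_ellipsoid(rng, n, semi_axes):
    """Uniform points inside an axis-aligned ellipsoid at the origin."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii = rng.random(n) ** (1.0 / 3.0)
    return v * radii[:, None] * np.asarray(semi_axes)


def _nb_mean(rng, mean, sd):
    """Gamma-Poisson mean intensity: a draw of the per-cluster expected
    blinking budget whose marginal is negative-binomial-like."""
    var = sd ** 2
    if var <= mean:
        return float(mean)
    shape = mean ** 2 / (var - mean)
    return float(rng.gamma(shape, (var - mean) / mean))


def _ellipsoid_z_halfwidth(rot, semi_axes):
    """Half-extent of the rotated ellipsoid along the z axis."""
    return float(np.sqrt(np.sum((rot[2] * np.asarray(semi_axes)) ** 2)))


def _draw_cluster_geometry(rng, spec: SceneSpec):
    fx, fy = (s * 1000.0 for s in spec.field_of_view)
    fz = spec.z_extent * 1000.0
    rows = []
    for i in range(spec.n_clusters):
        length = float(rng.lognormal(np.log(spec.cluster_length_median),
                                     spec.cluster_length_sigma))
        a = length / 2.0
        b = spec.cluster_aspect * a
        rot = _random_rotation(rng)
        rows.append({"cluster_id": i, "length": length, "width": 2 * b,
                     "semi_a": a, "semi_b": b, "rot": rot,
                     "rz": _ellipsoid_z_halfwidth(rot, (a, b, b)),
                     "mu": _nb_mean(rng, spec.locs_per_cluster_mean,
                                    spec.locs_per_cluster_sd)})
    # which clusters straddle a z border is size-determined, as in a
    # physical section whose thickness is comparable to the structures:
    # the axially largest clusters cannot avoid the borders.  Straddlers
    # keep their center inside the block with the far tip crossing the
    # border — the classic truncated cluster "extending beyond its upper
    # edge".  The combination makes the truncated subpopulation run
    # large, so filtering it out *lowers* the median volume, the
    # selection effect seen in thin-section data.
    n_trunc = int(round(spec.truncation_fraction * spec.n_clusters))
    straddle_ids: set = set()
    if n_trunc > 0 and rows:
        rz = np.array([g["rz"] for g in rows])
        straddle_ids = set(np.argsort(rz)[::-1][:n_trunc].tolist())
    for i, g in enumerate(rows):
        a, rz = g["semi_a"], g["rz"]
        g["cx"] = rng.uniform(a, fx - a)
        g["cy"] = rng.uniform(a, fy - a)
        g["straddling"] = i in straddle_ids or 2 * rz >= fz
        if g["straddling"]:
            border = fz if rng.random() < 0.5 else 0.0
            inward = 1.0 if border == 0.0 else -1.0
            g["cz"] = border + inward * rng.uniform(0.1, 0.9) * rz
        else:
            g["cz"] = rng.uniform(rz, fz - rz)
        del g["rz"]
    return rows, (fx, fy, fz)


def simulate_calibration_stack(model: DefocusModel | None = None,
                               z_min: float = -800.0, z_max: float = 800.0,
                               n_frames: int = 400, n_beads: int = 10,
                               width_noise: float = 0.0,
                               seed: int = 0) -> LocalizationTable:
    """Bead stack swept axially at constant speed for calibration.

    Each frame maps to one stage z (linear in frame); every bead yields
    one localization per frame with widths from the defocus model plus
    Gaussian width noise.  The ``stage_z`` column records the known
    stage position.
    """
    model = model or DefocusModel()
    rng = np.random.default_rng(seed)
    z = np.linspace(z_min, z_max, n_frames)
    frames = np.repeat(np.arange(n_frames), n_beads)
    stage = np.repeat(z, n_beads)
    bead_xy = rng.uniform(1000.0, 24_000.0, size=(n_beads, 2))
    xy = np.tile(bead_xy, (n_frames, 1))
    # stage_z is recorded on the emitter-defocus axis: positive stage_z
    # means the bead sits above the focal plane, matching the sign of
    # the astigmatic offset looked up for sample localizations
    wx, wy = model.widths(stage)
    if width_noise > 0:
        wx = wx + rng.normal(0, width_noise, size=wx.shape)
        wy = wy + rng.normal(0, width_noise, size=wy.shape)
    df = pd.DataFrame({
        "x": xy[:, 0], "y": xy[:, 1], "frame": frames,
        "intensity": np.full(len(frames), 30_000.0),
        "background": np.full(len(frames), 500.0),
        "width_x": np.clip(wx, 1.0, None),
        "width_y": np.clip(wy, 1.0, None),
        "stage_z": stage, "channel": "bead"})
    return LocalizationTable(df=df, metadata={"kind": "calibration_stack",
                                              "seed": seed})


def simulate_scene(spec: SceneSpec, model: DefocusModel | None = None):
    """Full scanning acquisition of one synthetic scene.

    Returns ``(movies, beads_pre, beads_post, truth)``: one localization
    table per scan (PSF widths but no z — computing z is the pipeline's
    job), bead recordings at both ends of the acquisition, and the
    complete ground truth.  Same spec and seed give identical output.
    """
    model = model or DefocusModel()
    rng = np.random.default_rng(spec.seed)
    scan = spec.scan_spec()
    geo, (fx, fy, fz) = _draw_cluster_geometry(rng, spec)
    drift = np.asarray(spec.drift, dtype=float)
    sig_lat, sig_ax = spec.precision
    survival = (1 - spec.bleach_per_scan) ** np.arange(scan.n_scans)
    w_total = survival.sum()

    # emitters per cluster sized so the expected blinking budget is mu
    emitters, owner = [], []
    for g in geo:
        n_em = max(3, int(round(g["mu"] / (spec.blinks_per_pass * w_total))))
        pts = _sample_ellipsoid(rng, n_em, (g["semi_a"], g["semi_b"],
                                            g["semi_b"]))
        pts = pts @ g["rot"].T + np.array([g["cx"], g["cy"], g["cz"]])
        # section boundaries: emitters outside the imaged z block are cut
        keep = (pts[:, 2] >= 0) & (pts[:, 2] <= fz)
        pts = pts[keep]
        emitters.append(pts)
        owner.append(np.full(len(pts), g["cluster_id"]))
        g["feret"] = _feret(pts)
    em_pos = np.concatenate(emitters) if emitters else np.empty((0, 3))
    em_owner = (np.concatenate(owner) if owner
                else np.empty(0, dtype=np.int64)).astype(np.int64)
    n_em_total = len(em_pos)
    # geometric bleaching: number of scans each emitter survives
    if n_em_total and spec.bleach_per_scan > 0:
        lifetime = rng.geometric(spec.bleach_per_scan, size=n_em_total)
    else:
        lifetime = np.full(n_em_total, scan.n_scans + 1)

    speed = scan.z_travel_nm / (scan.frames_per_movie - 1)  # nm per frame
    half_frames = spec.capture_halfwidth / speed
    counts_emitted = np.zeros(spec.n_clusters, dtype=np.int64)
    movies, labels = [], []
    bg_volume = fx * fy * fz / 1e9  # um^3
    n_bg_total = rng.poisson(spec.background_density * bg_volume)
    bg_scan = rng.integers(0, scan.n_scans, size=n_bg_total)

    for s in range(scan.n_scans):
        rows_x, rows_y, rows_f, rows_wx, rows_wy, rows_lab = \
            [], [], [], [], [], []
        alive = lifetime > s
        if alive.any():
            idx = np.flatnonzero(alive)
            nblink = rng.poisson(spec.blinks_per_pass, size=len(idx))
            rep = np.repeat(idx, nblink)
            if len(rep):
                pos = em_pos[rep]
                x, f, wx, wy, ok = _detect(rng, pos, s, scan, spec, model,
                                           drift, sig_lat, sig_ax,
                                           half_frames, speed)
                lab = em_owner[rep][ok]
                rows_x.append(x[:, 0]); rows_y.append(x[:, 1])
                rows_f.append(f); rows_wx.append(wx); rows_wy.append(wy)
                rows_lab.append(lab)
                np.add.at(counts_emitted, lab, 1)
        n_bg = int((bg_scan == s).sum())
        if n_bg:
            pos = np.column_stack([rng.uniform(0, fx, n_bg),
                                   rng.uniform(0, fy, n_bg),
                                   rng.uniform(0, fz, n_bg)])
            x, f, wx, wy, ok = _detect(rng, pos, s, scan, spec, model,
                                       drift, sig_lat, sig_ax,
                                       half_frames, speed)
            rows_x.append(x[:, 0]); rows_y.append(x[:, 1])
            rows_f.append(f); rows_wx.append(wx); rows_wy.append(wy)
            rows_lab.append(np.full(len(f), -1, dtype=np.int64))
        if rows_x:
            x = np.concatenate(rows_x)
            y = np.concatenate(rows_y)
            f = np.concatenate(rows_f)
            wx = np.concatenate(rows_wx)
            wy = np.concatenate(rows_wy)
            lab = np.concatenate(rows_lab)
        else:
            x = y = f = wx = wy = np.empty(0)
            lab = np.empty(0, dtype=np.int64)
        order = np.argsort(f, kind="stable")
        n = len(order)
        df = pd.DataFrame({
            "x": x[order], "y": y[order],
            "frame": f[order].astype(np.int64), "movie_id": s,
            "intensity": rng.lognormal(np.log(14_000.0), 0.35, n),
            "background": np.clip(rng.normal(1250.0, 150.0, n), 1.0, None),
            "width_x": np.clip(wx[order], 1.0, None),
            "width_y": np.clip(wy[order], 1.0, None),
            "channel": "bassoon"})
        movies.append(LocalizationTable(
            df=df, field_of_view=(fx, fy),
            metadata={"kind": "scan_movie", "scan": s, "seed": spec.seed}))
        labels.append(lab[order])

    bead_pos = np.column_stack([
        rng.uniform(500.0, fx - 500.0, spec.n_beads),
        rng.uniform(500.0, fy - 500.0, spec.n_beads),
        np.zeros(spec.n_beads)])
    beads_pre = _bead_table(rng, bead_pos, drift, 0.0, spec, fx, fy)
    beads_post = _bead_table(rng, bead_pos, drift, 1.0, spec, fx, fy)

    truth_rows = []
    for g in geo:
        truth_rows.append({
            "cluster_id": g["cluster_id"], "cx": g["cx"], "cy": g["cy"],
            "cz": g["cz"], "length": g["length"], "width": g["width"],
            "feret": g["feret"],
            "ux": g["rot"][0, 0], "uy": g["rot"][1, 0],
            "uz": g["rot"][2, 0],
            "count": int(counts_emitted[g["cluster_id"]]),
            "straddling": g["straddling"]})
    truth = SceneTruth(clusters=pd.DataFrame(truth_rows), beads=bead_pos,
                       drift=drift, spec=spec, loc_labels=labels)
    return movies, beads_pre, beads_post, truth


def _detect(rng, pos, s, scan, spec, model, drift, sig_lat, sig_ax,
            half_frames, speed):
    """Turn emitter positions into detections within one scan.

    Picks a uniform frame inside each emitter's in-focus window, applies
    drift at the global time of that frame, astigmatic widths at the
    resulting defocus, and localization noise.
    """
    n = len(pos)
    nf = scan.frames_per_movie
    # frame at which the stage passes the emitter's z
    if scan.alternate_direction and s % 2 == 1:
        f_center = (scan.z_start + scan.z_travel_nm - pos[:, 2]) / speed
    else:
        f_center = (pos[:, 2] - scan.z_start) / speed
    f_lo = np.ceil(f_center - half_frames)
    f_hi = np.floor(f_center + half_frames)
    f_lo = np.clip(f_lo, 0, nf - 1)
    f_hi = np.clip(f_hi, 0, nf - 1)
    ok = f_hi >= f_lo
    pos = pos[ok]
    f = (f_lo[ok] + np.floor(
        rng.random(int(ok.sum())) * (f_hi[ok] - f_lo[ok] + 1))).astype(int)
    t = global_time_fraction(f, s, scan)
    drifted = pos + t[:, None] * drift[None, :]
    dz = drifted[:, 2] - stage_z(f, s, scan)
    wx, wy = model.widths(dz)
    if spec.width_noise > 0:
        wx = wx + rng.normal(0, spec.width_noise, len(f))
        wy = wy + rng.normal(0, spec.width_noise, len(f))
    noise = np.column_stack([rng.normal(0, sig_lat, len(f)),
                             rng.normal(0, sig_lat, len(f)),
                             np.zeros(len(f))])
    return drifted + noise, f, wx, wy, ok


def _bead_table(rng, bead_pos, drift, t, spec, fx, fy):
    pos = bead_pos + t * drift[None, :]
    rep = np.repeat(pos, spec.bead_locs, axis=0)
    noisy = rep + rng.normal(0, spec.bead_sigma, rep.shape)
    df = pd.DataFrame({
        "x": noisy[:, 0], "y": noisy[:, 1], "z": noisy[:, 2],
        "frame": np.tile(np.arange(spec.bead_locs), len(bead_pos)),
        "intensity": np.full(len(rep), 30_000.0),
        "background": np.full(len(rep), 500.0),
        "channel": "bead"})
    return LocalizationTable(df=df, field_of_view=(fx, fy),
                             metadata={"kind": "beads",
                                       "epoch": "pre" if t == 0 else "post"})


def simulate_point_cloud(spec: SceneSpec):
    """Direct volumetric point cloud (no scanning), as from a 3D
    recording of a thin section: cluster localizations with z, jittered
    by the localization precision, plus uniform background, in random
    acquisition order.  Returns ``(table, truth)``.
    """
    rng = np.random.default_rng(spec.seed)
    geo, (fx, fy, fz) = _draw_cluster_geometry(rng, spec)
    sig_lat, sig_ax = spec.precision
    xs, labs = [], []
    truth_rows = []
    for g in geo:
        n = rng.poisson(g["mu"])
        pts = _sample_ellipsoid(rng, n, (g["semi_a"], g["semi_b"],
                                         g["semi_b"]))
        pts = pts @ g["rot"].T + np.array([g["cx"], g["cy"], g["cz"]])
        pts = pts[(pts[:, 2] >= 0) & (pts[:, 2] <= fz)]
        noisy = pts + np.column_stack([
            rng.normal(0, sig_lat, len(pts)),
            rng.normal(0, sig_lat, len(pts)),
            rng.normal(0, sig_ax, len(pts))])
        xs.append(noisy)
        labs.append(np.full(len(pts), g["cluster_id"], dtype=np.int64))
        truth_rows.append({
            "cluster_id": g["cluster_id"], "cx": g["cx"], "cy": g["cy"],
            "cz": g["cz"], "length": g["length"], "width": g["width"],
            "feret": _feret(pts),
            "ux": g["rot"][0, 0], "uy": g["rot"][1, 0],
            "uz": g["rot"][2, 0], "count": len(pts),
            "straddling": g["straddling"]})
    n_bg = rng.poisson(spec.background_density * fx * fy * fz / 1e9)
    bg = np.column_stack([rng.uniform(0, fx, n_bg),
                          rng.uniform(0, fy, n_bg),
                          rng.uniform(0, fz, n_bg)])
    xs.append(bg)
    labs.append(np.full(n_bg, -1, dtype=np.int64))
    pts = np.concatenate(xs) if xs else np.empty((0, 3))
    lab = np.concatenate(labs)
    perm = rng.permutation(len(pts))
    pts, lab = pts[perm], lab[perm]
    df = pd.DataFrame({
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "frame": rng.integers(0, 15_000, len(pts)),
        "movie_id": 0,
        "intensity": rng.lognormal(np.log(14_000.0), 0.35, len(pts)),
        "background": np.clip(rng.normal(1250.0, 150.0, len(pts)),
                              1.0, None),
        "channel": "bassoon"})
    table = LocalizationTable(df=df, field_of_view=(fx, fy),
                              metadata={"kind": "point_cloud",
                                        "seed": spec.seed})
    truth = SceneTruth(clusters=pd.DataFrame(truth_rows),
                       beads=np.empty((0, 3)),
                       drift=np.zeros(3), spec=spec, loc_labels=[lab])
    return table, truth


def scene_truth_table(truth: SceneTruth) -> pd.DataFrame:
    """Per-cluster ground-truth metrics for recovery scoring."""
    return truth.clusters.copy()


def expected_isosurface_volume(truth_row, spec: SceneSpec,
                               params: ClusterParams, iso_threshold: float,
                               fine_voxel: float = 10.0) -> float:
    """Expected segmented volume (um^3) of one true cluster.

    The segmentation measures the volume of the density super-level set,
    which depends on the rendering kernel and threshold, not on the bare
    ellipsoid.  This computes it from truth: the analytic emitter
    density (uniform ellipsoid scaled to the true count, convolved with
    the rendering kernel broadened by the localization precision) is
    evaluated on a fine local grid and thresholded.
    """
    a = truth_row["length"] / 2.0
    b = truth_row["width"] / 2.0
    count = truth_row["count"]
    u = np.array([truth_row["ux"], truth_row["uy"], truth_row["uz"]])
    sig_k = np.atleast_1d(np.asarray(params.kernel_sigma, dtype=float))
    if sig_k.size == 1:
        sig_k = np.repeat(sig_k, 3)
    sig_lat, sig_ax = spec.precision
    sig_eff = np.sqrt(sig_k ** 2 + np.array([sig_lat, sig_lat, sig_ax]) ** 2)
    pad = a + 4 * sig_eff.max()
    n = int(np.ceil(2 * pad / fine_voxel))
    axes = [np.arange(n) * fine_voxel - pad + fine_voxel / 2] * 3
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    # orthonormal frame with u as the major axis
    v = np.array([1.0, 0.0, 0.0])
    if abs(u @ v) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(u, v)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(u, e2)
    p1 = gx * u[0] + gy * u[1] + gz * u[2]
    p2 = gx * e2[0] + gy * e2[1] + gz * e2[2]
    p3 = gx * e3[0] + gy * e3[1] + gz * e3[2]
    inside = ((p1 / a) ** 2 + (p2 / b) ** 2 + (p3 / b) ** 2) <= 1.0
    ell_vol_um3 = (4.0 / 3.0) * np.pi * a * b * b / 1e9
    dens = inside.astype(float) * (count / ell_vol_um3)
    dens = ndimage.gaussian_filter(dens, sigma=sig_eff / fine_voxel)
    return float((dens >= iso_threshold).sum() * fine_voxel ** 3 / 1e9)
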