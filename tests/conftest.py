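"""Shared fixtures: a small simulated acquisition run end-to-end once per
session, a noiseless calibration, and helpers for constructed tables."""

import numpy as np
import pandas as pd
import pytest

import volstorm as vs
from volstorm.table import LocalizationTable


@pytest.fixture(scope="session")
def calib():
    """Noiseless astigmatic calibration over +/- 800 nm."""
    stack = vs.simulate_calibration_stack(width_noise=0.0, seed=1)
    return vs.fit_calibration(stack)


@pytest.fixture(scope="session")
def small_spec():
    return vs.SceneSpec(field_of_view=(8.0, 8.0), z_extent=4.0,
                        n_clusters=15, background_density=0.5, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    movies, pre, post, truth = vs.simulate_scene(small_spec)
    return {"movies": movies, "pre": pre, "post": post, "truth": truth,
            "spec": small_spec}


@pytest.fixture(scope="session")
def small_run(small_scene, calib):
    """The small scene pushed through assemble -> drift -> denoise ->
    segment with default parameters."""
    spec = small_scene["spec"]
    scan = spec.scan_spec()
    vol = vs.assemble_volume(small_scene["movies"], scan, calib)
    tf = vs.estimate_transform(vs.summarize_beads(small_scene["pre"]),
                               vs.summarize_beads(small_scene["post"],
                                                  timestamp="post"))
    corrected = vs.correct_drift(vol, tf, scan)
    den = vs.denoise(corrected)
    result = vs.segment_clusters(den, vs.ClusterParams())
    return {"assembled": vol, "transform": tf, "corrected": corrected,
            "denoised": den, "result": result, "scan": scan, "spec": spec}


def make_table(points, **extra_cols):
    """LocalizationTable from an (n, 3) coordinate array (nm)."""
    points = np.asarray(points, dtype=float)
    df = pd.DataFrame({"x": points[:, 0], "y": points[:, 1],
                       "z": points[:, 2], "frame": 0})
    for k, v in extra_cols.items():
        df[k] = v
    return LocalizationTable(df=df)


@pytest.fixture
def blob_factory():
    """Well-separated Gaussian blobs for constructed segmentation cases."""
    def _make(centers, n_per, spread=25.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate([
            rng.normal(c, spread, size=(n, 3))
            for c, n in zip(np.atleast_2d(centers), np.atleast_1d(n_per))])
        return make_table(pts)
    return _make
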