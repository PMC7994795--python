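"""Fiducial summarization, transform estimation, drift correction and
round alignment."""

import numpy as np
import pandas as pd
import pytest

import volstorm as vs
from volstorm.drift import FiducialSet, RigidTransform
from volstorm.errors import FiducialError
from volstorm.table import LocalizationTable

from conftest import make_table


def _bead_cloud(centers, n_per=50, spread=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(c, spread, size=(n_per, 3))
                          for c in np.atleast_2d(centers)])
    return make_table(pts)


def _fids(positions):
    positions = np.atleast_2d(positions).astype(float)
    return FiducialSet(positions=positions,
                       spreads=np.zeros(len(positions)),
                       n_locs=np.full(len(positions), 50))


class TestSummarizeBeads:
    def test_recovers_three_separated_centers(self):
        centers = np.array([[1000.0, 1000.0, 0.0],
                            [5000.0, 1000.0, 0.0],
                            [1000.0, 6000.0, 0.0]])
        fids = vs.summarize_beads(_bead_cloud(centers, seed=1))
        assert len(fids) == 3
        order = np.argsort(fids.positions[:, 0] + fids.positions[:, 1])
        truth = centers[np.argsort(centers[:, 0] + centers[:, 1])]
        assert np.abs(fids.positions[order] - truth).max() < 5.0

    def test_centers_at_twice_merge_radius_stay_separate(self):
        centers = np.array([[0.0, 0.0, 0.0], [200.0, 0.0, 0.0]])
        fids = vs.summarize_beads(_bead_cloud(centers, spread=1.0),
                                  merge_radius=100.0)
        assert len(fids) == 2

    def test_too_few_localizations_is_fiducial_error(self):
        with pytest.raises(FiducialError):
            vs.summarize_beads(_bead_cloud([[0.0, 0.0, 0.0]], n_per=5))

    def test_empty_table_is_fiducial_error(self):
        df = pd.DataFrame({"x": [], "y": [], "frame": []})
        with pytest.raises(FiducialError):
            vs.summarize_beads(LocalizationTable(df=df))


class TestEstimateTransform:
    def test_exact_shift_recovered(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 20_000, size=(10, 3))
        shift = np.array([50.0, -30.0, 20.0])
        tf = vs.estimate_transform(_fids(pre), _fids(pre + shift))
        np.testing.assert_allclose(tf.translation, shift, atol=1e-9)
        assert tf.rms_residual < 1e-9 and tf.n_pairs == 10

    def test_identity_for_identical_sets(self):
        pre = np.random.default_rng(3).uniform(0, 10_000, size=(5, 3))
        tf = vs.estimate_transform(_fids(pre), _fids(pre))
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_noisy_translation_within_standard_error(self):
        rng = np.random.default_rng(4)
        pre = rng.uniform(0, 20_000, size=(20, 3))
        shift = np.array([50.0, -30.0, 20.0])
        post = pre + shift + rng.normal(0, 10.0, size=(20, 3))
        tf = vs.estimate_transform(_fids(pre), _fids(post))
        bound = 3 * 10.0 / np.sqrt(20)
        assert np.abs(tf.translation - shift).max() < bound

    def test_disjoint_sets_raise(self):
        a = np.zeros((3, 3))
        b = np.full((3, 3), 1e6)
        with pytest.raises(FiducialError):
            vs.estimate_transform(_fids(a + [[0, 0, 0], [3000, 0, 0],
                                             [0, 3000, 0]]), _fids(b))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        pre = rng.uniform(0, 20_000, size=(8, 3))
        post = pre + rng.normal(0, 5, size=(8, 3))
        t1 = vs.estimate_transform(_fids(pre), _fids(post))
        v = np.array([111.0, -222.0, 33.0])
        t2 = vs.estimate_transform(_fids(pre + v), _fids(post + v))
        np.testing.assert_allclose(t1.translation, t2.translation,
                                   atol=1e-8)


def test_transform_inverse_is_identity():
    tf = RigidTransform(translation=np.array([10.0, -5.0, 3.0]),
                        rotation=0.01, scale=1.002,
                        center=np.array([5000.0, 5000.0, 0.0]))
    pts = np.random.default_rng(6).uniform(0, 10_000, size=(50, 3))
    back = tf.inverse().apply(tf.apply(pts))
    assert np.abs(back - pts).max() < 1e-6


class TestCorrectDrift:
    def _table_with_time(self, pts, spec):
        n = len(pts)
        rng = np.random.default_rng(7)
        movie = rng.integers(0, spec.n_scans, n)
        frame = rng.integers(0, spec.frames_per_movie, n)
        df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                           "frame": frame, "movie_id": movie})
        return LocalizationTable(df=df), movie, frame

    def test_zero_transform_is_identity(self):
        spec = vs.ScanSpec(n_scans=2, frames_per_movie=100)
        pts = np.random.default_rng(8).uniform(0, 5000, size=(100, 3))
        table, _, _ = self._table_with_time(pts, spec)
        out = vs.correct_drift(table, RigidTransform(), spec)
        np.testing.assert_allclose(out.coords("xyz"), pts, atol=1e-12)

    def test_linear_drift_removed_exactly(self):
        from volstorm.scan import global_time_fraction
        spec = vs.ScanSpec(n_scans=4, frames_per_movie=1000)
        pts = np.random.default_rng(9).uniform(0, 5000, size=(300, 3))
        table, movie, frame = self._table_with_time(pts, spec)
        drift = np.array([60.0, 0.0, -40.0])
        t = global_time_fraction(frame, movie, spec)
        drifted = table.replace(table.df.assign(
            x=pts[:, 0] + t * drift[0], y=pts[:, 1] + t * drift[1],
            z=pts[:, 2] + t * drift[2]))
        out = vs.correct_drift(drifted,
                               RigidTransform(translation=drift), spec)
        rms = np.sqrt(np.mean((out.coords("xyz") - pts) ** 2))
        assert rms < 1e-9

    def test_step_drift_leaves_half_jump_at_discontinuity(self):
        # a constant jump at mid-acquisition corrected by the linear model
        from volstorm.scan import global_time_fraction
        spec = vs.ScanSpec(n_scans=2, frames_per_movie=1000)
        n = 1999
        frame = np.tile(np.arange(1000), 2)[:n]
        movie = np.repeat([0, 1], 1000)[:n]
        t = global_time_fraction(frame, movie, spec)
        jump = 80.0
        x = 1000.0 + np.where(t > 0.5, jump, 0.0)
        df = pd.DataFrame({"x": x, "y": 0.0, "z": 0.0,
                           "frame": frame, "movie_id": movie})
        out = vs.correct_drift(
            LocalizationTable(df=df),
            RigidTransform(translation=np.array([jump, 0.0, 0.0])), spec)
        resid = out.df["x"].to_numpy() - 1000.0
        at_jump = resid[np.argmin(np.abs(t - 0.5 - 1e-6))]
        assert abs(abs(at_jump) - jump / 2) < 1.0

    def test_order_and_count_preserved(self, small_run):
        corrected = small_run["corrected"]
        assembled = small_run["assembled"]
        assert len(corrected) == len(assembled)
        np.testing.assert_array_equal(corrected.df["frame"],
                                      assembled.df["frame"])


class TestAlignRounds:
    def test_pure_shift_alignment(self):
        rng = np.random.default_rng(10)
        ref = rng.uniform(0, 20_000, size=(10, 3))
        shift = np.array([100.0, 100.0, 0.0])
        table = make_table(rng.uniform(0, 20_000, size=(50, 3)))
        aligned = vs.align_rounds(table, _fids(ref + shift), _fids(ref))
        np.testing.assert_allclose(aligned.coords("xyz"),
                                   table.coords("xyz") - shift, atol=1e-9)

    def test_rotation_recovered_within_hundredth_degree(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(0, 20_000, size=(10, 3))
        angle = np.deg2rad(0.5)
        center = ref.mean(axis=0)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = (ref - center) @ rot.T + center + [120.0, -60.0, 10.0]
        tf = vs.estimate_transform(_fids(moved), _fids(ref),
                                   allow_rotation=True)
        assert abs(abs(tf.rotation) - angle) < np.deg2rad(0.01)
        np.testing.assert_allclose(tf.apply(moved), ref, atol=2.0)

    def test_disjoint_beads_raise(self):
        table = make_table(np.zeros((5, 3)))
        a = _fids([[0, 0, 0], [3000, 0, 0], [0, 3000, 0]])
        b = _fids([[1e6, 1e6, 0], [1e6 + 3000, 1e6, 0],
                   [1e6, 1e6 + 3000, 0]])
        with pytest.raises(FiducialError):
            vs.align_rounds(table, a, b)


def test_drift_corrector_estimator_round_trip(small_scene, small_run):
    spec = small_scene["spec"].scan_spec()
    est = vs.DriftCorrector(spec=spec)
    est.fit(small_scene["pre"], small_scene["post"])
    truth_drift = np.asarray(small_scene["spec"].drift)
    assert np.abs(est.transform_.translation - truth_drift).max() < 3.0
    out = est.transform(small_run["assembled"])
    np.testing.assert_allclose(out.coords("xyz"),
                               small_run["corrected"].coords("xyz"),
                               atol=1e-9)
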