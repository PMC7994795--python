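"""Denoising, segmentation metrics, truncation, subsampling, reduction."""

import numpy as np
import pandas as pd
import pytest

import volstorm as vs
from volstorm.clusters import Cluster
from volstorm.errors import ParameterError
from volstorm.table import LocalizationTable

from conftest import make_table


class TestDenoise:
    def test_isolated_point_is_noise(self):
        rng = np.random.default_rng(0)
        cluster = rng.normal(0, 30, size=(50, 3))
        stray = np.array([[5000.0, 5000.0, 5000.0]])
        table = make_table(np.vstack([cluster, stray]))
        out = vs.denoise(table, eps=100.0, min_pts=8)
        assert len(out) == 50
        assert out.metadata["denoise_removed"] == 1

    def test_constructed_separability(self):
        rng = np.random.default_rng(1)
        dense = rng.uniform(-50, 50, size=(100, 3))
        strays = rng.uniform(2000, 10_000, size=(20, 3))
        table = make_table(np.vstack([dense, strays]))
        out = vs.denoise(table, eps=100.0, min_pts=8)
        assert out.metadata["denoise_removed"] == 20
        assert np.abs(out.coords("xyz")).max() <= 50.0

    def test_empty_table_passes_through(self):
        table = make_table(np.empty((0, 3)))
        assert len(vs.denoise(table)) == 0


class TestSegmentation:
    def test_two_separated_ellipsoids(self):
        rng = np.random.default_rng(2)
        a = rng.normal([2000, 2000, 1000], [150, 40, 40], size=(100, 3))
        b = rng.normal([4000, 2000, 1000], [150, 40, 40], size=(100, 3))
        res = vs.segment_clusters(make_table(np.vstack([a, b])),
                                  vs.ClusterParams(iso_threshold=100.0))
        assert len(res.clusters) == 2
        counts = sorted(c.count for c in res.clusters)
        assert counts[0] >= 98 and counts[1] <= 100

    def test_two_point_cluster_has_exact_feret_length(self):
        pts = np.array([[1000.0, 1000.0, 1000.0],
                        [1300.0, 1000.0, 1000.0]])
        params = vs.ClusterParams(kernel_sigma=(120.0, 120.0, 120.0),
                                  iso_threshold=5.0, min_count=2)
        res = vs.segment_clusters(make_table(pts), params)
        assert len(res.clusters) == 1
        assert res.clusters[0].length == pytest.approx(300.0, abs=1e-9)
        assert res.clusters[0].count == 2

    def test_min_count_cutoff_is_inclusive(self):
        rng = np.random.default_rng(3)
        sizes = [5, 8, 20]
        blobs = [rng.normal([2000 + 3000 * i, 2000, 1000], 30, size=(n, 3))
                 for i, n in enumerate(sizes)]
        res = vs.segment_clusters(
            make_table(np.vstack(blobs)),
            vs.ClusterParams(iso_threshold=50.0, min_count=8))
        assert sorted(c.count for c in res.clusters) == [8, 20]
        assert res.n_dropped_clusters == 1
        assert res.n_dropped_locs == 5

    def test_count_conservation(self, small_run):
        res = small_run["result"]
        total = sum(c.count for c in res.clusters)
        assert total + res.n_unassigned + res.n_dropped_locs == res.n_input
        assert res.n_input == len(small_run["denoised"])

    def test_density_is_count_over_volume_exactly(self, small_run):
        for c in small_run["result"].clusters:
            assert c.density == c.count / c.volume
            assert c.count == len(c.member_ids)
            assert c.length >= c.width >= 0.0

    def test_empty_input_gives_empty_result(self):
        res = vs.segment_clusters(make_table(np.empty((0, 3))),
                                  vs.ClusterParams(iso_threshold=10.0))
        assert res.clusters == [] and res.n_input == 0

    def test_volume_converges_under_voxel_refinement(self):
        rng = np.random.default_rng(4)
        pts = rng.normal([2000, 2000, 1000], [150, 50, 50], size=(300, 3))
        table = make_table(pts)
        vols = {}
        for vox in (20.0, 10.0):
            res = vs.segment_clusters(
                table, vs.ClusterParams(voxel_size=vox, iso_threshold=200.0))
            assert len(res.clusters) == 1
            vols[vox] = res.clusters[0].volume
        assert abs(vols[10.0] - vols[20.0]) / vols[20.0] < 0.05

    def test_dbscan_mode_segments_blobs(self, blob_factory):
        table = blob_factory([[1000, 1000, 1000], [5000, 5000, 1000]],
                             [60, 60], seed=5)
        res = vs.segment_clusters(table, vs.ClusterParams(),
                                  method="dbscan")
        assert len(res.clusters) == 2
        for c in res.clusters:
            assert c.volume > 0 and c.density == c.count / c.volume


def _cluster_with_bounds(zmin, zmax):
    return Cluster(cluster_id=0, member_ids=np.arange(3), count=3,
                   centroid=np.array([0.0, 0.0, (zmin + zmax) / 2]),
                   length=100.0, width=10.0, volume=1e-3, density=3e3,
                   bounds_min=np.array([0.0, 0.0, zmin]),
                   bounds_max=np.array([100.0, 100.0, zmax]))


class TestTruncation:
    def test_cluster_near_face_is_flagged(self):
        c = _cluster_with_bounds(5.0, 400.0)
        vs.flag_truncation([c], {"z": (0.0, 1000.0)}, margin=20.0)
        assert c.truncated

    def test_interior_cluster_is_not_flagged(self):
        c = _cluster_with_bounds(200.0, 800.0)
        vs.flag_truncation([c], {"z": (0.0, 1000.0)}, margin=20.0)
        assert not c.truncated

    def test_only_requested_axes_checked(self):
        c = _cluster_with_bounds(200.0, 800.0)  # x starts at 0
        vs.flag_truncation([c], ((0.0, 1000.0), (0.0, 1000.0),
                                 (0.0, 1000.0)), margin=20.0, axes=("z",))
        assert not c.truncated
        vs.flag_truncation([c], ((0.0, 1000.0), (0.0, 1000.0),
                                 (0.0, 1000.0)), margin=20.0,
                           axes=("x", "z"))
        assert c.truncated


class TestSubsample:
    @pytest.mark.parametrize("fraction,expected", [
        (0.5, [0, 2, 4, 6, 8]),
        (0.9, [0, 1, 2, 3, 4, 5, 6, 7, 8]),
        (0.8, [0, 1, 2, 3, 5, 6, 7, 8]),
        (0.66, [0, 1, 3, 4, 6, 7, 9]),
        (0.33, [0, 3, 6, 9]),
        (0.2, [0, 5]),
        (0.1, [0]),
    ])
    def test_exact_deterministic_schemes(self, fraction, expected):
        table = make_table(np.column_stack(
            [np.arange(10), np.zeros(10), np.zeros(10)]))
        out = vs.subsample(table, fraction)
        assert out.df["x"].astype(int).tolist() == expected

    def test_full_fraction_is_identity(self):
        table = make_table(np.random.default_rng(0).uniform(size=(20, 3)))
        out = vs.subsample(table, 1.0)
        np.testing.assert_array_equal(out.coords("xyz"),
                                      table.coords("xyz"))

    def test_unsupported_fraction_rejected(self):
        with pytest.raises(ParameterError):
            vs.subsample(make_table(np.zeros((5, 3))), 0.42)


class TestReduction:
    def test_identical_groups_give_p_of_one(self, blob_factory):
        table = blob_factory([[1000, 1000, 1000]], [120], seed=6)
        res = vs.reduction_experiment(
            table, vs.ClusterParams(iso_threshold=100.0, min_count=8),
            fractions=(1.0, 1.0, 1.0))
        assert res.kruskal_p == pytest.approx(1.0)

    def test_threshold_scales_proportionally(self, blob_factory):
        table = blob_factory(
            [[1000, 1000, 1000], [4000, 4000, 1000]], [150, 150], seed=7)
        res = vs.reduction_experiment(
            table, vs.ClusterParams(iso_threshold=300.0, min_count=8),
            fractions=(1.0, 0.5))
        # noise-free constructed scene: same cluster count at both
        assert res.n_clusters[1.0] == res.n_clusters[0.5] == 2


class TestDepthProfile:
    def test_ratio_column_semantics(self):
        table = make_table(np.zeros((1, 3)), intensity=11_000.0,
                           background=1000.0)
        prof = vs.depth_profile(table, n_bins=1)
        assert prof["median_intensity_over_background"].iloc[0] == \
            pytest.approx(11.0)

    def test_single_bin_is_global_median(self):
        rng = np.random.default_rng(8)
        table = make_table(rng.uniform(0, 1000, size=(100, 3)),
                           intensity=rng.uniform(1e4, 4e4, 100),
                           background=rng.uniform(500, 1500, 100))
        prof = vs.depth_profile(table, n_bins=1)
        assert prof["median_intensity"].iloc[0] == pytest.approx(
            np.median(table.df["intensity"]))
        assert prof["count"].iloc[0] == 100

    def test_depth_homogeneous_scene_shows_flat_profile(self):
        from scipy.stats import kruskal
        rng = np.random.default_rng(9)
        n = 3000
        z = rng.uniform(0, 10_000, n)
        table = make_table(
            np.column_stack([rng.uniform(0, 1000, n),
                             rng.uniform(0, 1000, n), z]),
            intensity=rng.lognormal(np.log(14_000), 0.35, n),
            background=rng.normal(1250, 150, n))
        prof = vs.depth_profile(table, n_bins=5)
        edges = np.linspace(z.min(), z.max() + 1e-9, 6)
        groups = [table.df["intensity"][(z >= lo) & (z < hi)].to_numpy()
                  for lo, hi in zip(edges[:-1], edges[1:])]
        assert kruskal(*groups).pvalue > 0.05
        assert prof["count"].sum() == n
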