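"""Bouton reconstruction from membrane shells and cluster assignment."""

import numpy as np
import pandas as pd
import pytest

import volstorm as vs
from volstorm.clusters import Cluster

from conftest import make_table

PARAMS = vs.ClusterParams(voxel_size=40.0, kernel_sigma=(50.0, 50.0, 80.0))


def _shell(rng, center, axes, n, noise=30.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(axes) + rng.normal(0, noise, (n, 3)) + center


def _cluster_at(point, cid=0):
    return Cluster(cluster_id=cid, member_ids=np.arange(5), count=5,
                   centroid=np.asarray(point, dtype=float), length=300.0,
                   width=60.0, volume=0.01, density=500.0)


@pytest.fixture(scope="module")
def single_shell():
    rng = np.random.default_rng(3)
    axes = (2000.0, 1200.0, 800.0)
    pts = _shell(rng, [5000.0, 5000.0, 4000.0], axes, 6000)
    table = make_table(pts)
    surfaces = vs.reconstruct_boutons(table, PARAMS, min_volume=1.0)
    truth = 4.0 / 3.0 * np.pi * np.prod(axes) / 1e9
    return surfaces, truth


def test_single_shell_volume_within_20pct(single_shell):
    surfaces, truth = single_shell
    assert len(surfaces) == 1
    assert surfaces[0].volume == pytest.approx(truth, rel=0.20)
    assert surfaces[0].volume == len(surfaces[0].voxel_keys) * \
        surfaces[0].grid.voxel_volume_um3


def test_two_shells_with_axon_tube_split_by_seeds():
    rng = np.random.default_rng(4)
    axes = (1500.0, 1000.0, 800.0)
    p1 = _shell(rng, [4000.0, 4000.0, 3000.0], axes, 5000)
    p2 = _shell(rng, [11_000.0, 4000.0, 3000.0], axes, 5000)
    tx = np.linspace(5600, 9400, 800)
    tube = np.column_stack([tx, np.full(800, 4000.0),
                            np.full(800, 3000.0)]) \
        + rng.normal(0, 60, (800, 3))
    table = make_table(np.vstack([p1, p2, tube]))
    seeds = pd.DataFrame({"bouton_id": [7, 9],
                          "x_nm": [4000.0, 11_000.0],
                          "y_nm": [4000.0, 4000.0],
                          "z_nm": [3000.0, 3000.0]})
    surfaces = vs.reconstruct_boutons(table, PARAMS, min_volume=1.0,
                                      seeds=seeds)
    assert [s.bouton_id for s in surfaces] == [7, 9]
    # masks are disjoint and the tube is split near its middle
    keys = [set(s.voxel_keys.tolist()) for s in surfaces]
    assert not keys[0] & keys[1]
    assert surfaces[0].volume == pytest.approx(surfaces[1].volume, rel=0.2)


def test_empty_membrane_table_gives_no_boutons():
    table = make_table(np.empty((0, 3)))
    assert vs.reconstruct_boutons(table, PARAMS) == []


def test_nothing_above_min_volume_gives_no_boutons():
    rng = np.random.default_rng(5)
    pts = _shell(rng, [2000.0, 2000.0, 2000.0], (300.0, 300.0, 300.0), 400)
    assert vs.reconstruct_boutons(make_table(pts), PARAMS,
                                  min_volume=5.0) == []


class TestAssignment:
    def test_inside_outside_and_tally(self, single_shell):
        surfaces, _ = single_shell
        inside = _cluster_at([5000.0, 5000.0, 4000.0], 0)
        outside = _cluster_at([100.0, 100.0, 100.0], 1)
        vs.assign_clusters([inside, outside], surfaces)
        assert inside.bouton_id == surfaces[0].bouton_id
        assert outside.bouton_id is None
        assert surfaces[0].n_clusters == 1

    def test_boundary_voxel_counts_as_inside(self, single_shell):
        surfaces, _ = single_shell
        b = surfaces[0]
        edge_voxel = b.grid.unkey(b.voxel_keys[:1])[0]
        center = b.grid.voxel_centers(edge_voxel[None, :])[0]
        c = _cluster_at(center)
        vs.assign_clusters([c], surfaces)
        assert c.bouton_id == b.bouton_id

    def test_assignment_conservation(self, single_shell):
        surfaces, _ = single_shell
        rng = np.random.default_rng(6)
        clusters = [_cluster_at(p, i) for i, p in enumerate(
            rng.uniform(0, 10_000, size=(40, 3)))]
        vs.assign_clusters(clusters, surfaces)
        assigned = sum(s.n_clusters for s in surfaces)
        unassigned = sum(c.bouton_id is None for c in clusters)
        assert assigned + unassigned == len(clusters)


class TestPerBoutonSummary:
    def _boutons(self, volumes):
        from volstorm.boutons import BoutonSurface
        from volstorm.density import Grid
        grid = Grid((0.0, 0.0, 0.0), 40.0, (10, 10, 10))
        return [BoutonSurface(bouton_id=i, voxel_keys=np.array([i]),
                              grid=grid, volume=v,
                              centroid=np.zeros(3))
                for i, v in enumerate(volumes)]

    def _clusters_for(self, counts):
        out = []
        cid = 0
        for b, n in enumerate(counts):
            for _ in range(n):
                c = _cluster_at([0, 0, 0], cid)
                c.bouton_id = b
                out.append(c)
                cid += 1
        return out

    def test_monotone_association_gives_r_one(self):
        boutons = self._boutons([1.0, 2.0, 4.0, 8.0, 16.0])
        clusters = self._clusters_for([1, 2, 3, 5, 8])
        df, corr = vs.per_bouton_summary(clusters, boutons)
        assert len(df) == 5
        assert corr[0] == pytest.approx(1.0)

    def test_anti_monotone_gives_r_minus_one(self):
        boutons = self._boutons([16.0, 8.0, 4.0, 2.0, 1.0])
        clusters = self._clusters_for([1, 2, 3, 5, 8])
        _, corr = vs.per_bouton_summary(clusters, boutons)
        assert corr[0] == pytest.approx(-1.0)

    def test_fewer_than_three_boutons_omits_correlation(self):
        boutons = self._boutons([1.0, 2.0])
        _, corr = vs.per_bouton_summary(self._clusters_for([1, 2]), boutons)
        assert corr is None
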