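"""Lesion-derived structural metrics against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from strokebeta.lesions import (COMMISSURAL_TRACTS, PROJECTION_TRACTS,
                                ParcelAtlas, StreamlineAtlas, VoxelGrid,
                                disconnection_map,
                                extract_structural_features,
                                flip_and_smooth, lesion_volume, roi_damage,
                                sspl_delta, tract_disconnection)


def random_fixture(rng, shape=(12, 12, 12), n_parcels=4, n_streams=30):
    """Random grid/atlas/streamline triple for oracle comparisons."""
    labels = np.zeros(shape, dtype=int)
    names = {}
    for pid in range(1, n_parcels + 1):
        c = rng.integers(1, np.array(shape) - 2)
        labels[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2] = pid
        names[pid] = f"P{pid}"
    # ensure non-empty parcels after overwrites
    for pid in list(names):
        if not (labels == pid).any():
            labels[pid, pid, pid] = pid
    atlas = ParcelAtlas(labels=labels, names=names)
    streams, tracts = [], []
    parcel_voxels = {pid: np.argwhere(labels == pid) for pid in names}
    for k in range(n_streams):
        a, b = rng.choice(list(names), size=2, replace=False)
        va = parcel_voxels[a][rng.integers(len(parcel_voxels[a]))]
        vb = parcel_voxels[b][rng.integers(len(parcel_voxels[b]))]
        pts = np.clip(np.round(np.linspace(va, vb, 8)
                               + rng.integers(-1, 2, size=(8, 3))),
                      0, np.array(shape) - 1).astype(int)
        pts[0], pts[-1] = va, vb
        streams.append(pts)
        tracts.append(f"T{k % 5}")
    sa = StreamlineAtlas(streamlines=streams, tract_labels=tracts,
                         shape=shape)
    mask = (rng.random(shape) < 0.08).astype(np.uint8)
    grid = VoxelGrid(mask=mask, voxel_size=(1.0, 2.0, 1.5))
    return grid, atlas, sa


class TestVolumes:
    def test_empty_mask(self):
        g = VoxelGrid(mask=np.zeros((4, 4, 4)), voxel_size=(1, 1, 1))
        assert lesion_volume(g) == 0.0

    def test_ten_unit_voxels(self):
        m = np.zeros((5, 5, 5))
        m.flat[:10] = 1
        assert lesion_volume(VoxelGrid(mask=m, voxel_size=(1, 1, 1))) == 10.0

    def test_counting_oracle(self, rng):
        for _ in range(20):
            m = (rng.random((6, 7, 8)) < 0.3).astype(int)
            g = VoxelGrid(mask=m, voxel_size=(1.5, 2.0, 1.0))
            assert lesion_volume(g) == pytest.approx(m.sum() * 3.0)


class TestRoiDamage:
    def test_half_overlap(self):
        labels = np.zeros((6, 6, 6), dtype=int)
        labels[0, 0, :4] = 1
        atlas = ParcelAtlas(labels=labels, names={1: "roi"})
        m = np.zeros((6, 6, 6))
        m[0, 0, :2] = 1
        g = VoxelGrid(mask=m, voxel_size=(1, 1, 1))
        assert roi_damage(g, atlas, "roi") == 50.0

    def test_disjoint_lesion_zero(self, lesion_fixture):
        atlas, _, _ = lesion_fixture
        g = VoxelGrid(mask=np.zeros(atlas.labels.shape),
                      voxel_size=(2, 2, 2))
        assert roi_damage(g, atlas, "cM1") == 0.0

    def test_unknown_roi(self, lesion_fixture):
        atlas, _, grid = lesion_fixture
        with pytest.raises(KeyError):
            roi_damage(grid, atlas, "nope")

    def test_set_intersection_oracle(self, rng):
        for _ in range(20):
            grid, atlas, _ = random_fixture(rng)
            for name in atlas.names.values():
                roi_vox = set(map(tuple, np.argwhere(atlas.parcel_mask(name))))
                les_vox = set(map(tuple, np.argwhere(grid.mask)))
                expect = 100.0 * len(roi_vox & les_vox) / len(roi_vox)
                assert roi_damage(grid, atlas, name) == pytest.approx(expect)


class TestTractDisconnection:
    def test_all_or_nothing(self):
        shape = (5, 5, 5)
        s = StreamlineAtlas(
            streamlines=[np.array([[0, 0, 0], [1, 1, 1]]),
                         np.array([[2, 2, 2], [3, 3, 3]])],
            tract_labels=["t", "t"], shape=shape)
        full = VoxelGrid(mask=np.ones(shape), voxel_size=(1, 1, 1))
        empty = VoxelGrid(mask=np.zeros(shape), voxel_size=(1, 1, 1))
        assert tract_disconnection(full, s, "t") == 100.0
        assert tract_disconnection(empty, s, "t") == 0.0
        with pytest.raises(KeyError):
            tract_disconnection(full, s, "missing")

    def test_brute_force_oracle(self, rng):
        for _ in range(20):
            grid, _, sa = random_fixture(rng)
            for tract in sa.tracts:
                idx = sa.tract_indices(tract)
                hit = sum(
                    any(grid.mask[tuple(v)] for v in sa.streamlines[i])
                    for i in idx)
                assert tract_disconnection(grid, sa, tract) == \
                    pytest.approx(100.0 * hit / len(idx))


class TestDisconnectionMap:
    def test_quarter_voxel(self):
        shape = (4, 4, 4)
        streams = [np.array([[0, 0, 0], [1, 1, 1]])] + \
                  [np.array([[0, 0, 0], [2, 2, 2]])] * 3
        sa = StreamlineAtlas(streamlines=streams,
                             tract_labels=["t"] * 4, shape=shape)
        m = np.zeros(shape)
        m[1, 1, 1] = 1
        g = VoxelGrid(mask=m, voxel_size=(1, 1, 1))
        dm = disconnection_map(g, sa)
        assert dm[0, 0, 0] == 25.0       # 1 of 4 through-streamlines hit
        assert dm[1, 1, 1] == 100.0
        assert dm[3, 3, 3] == 0.0        # no streamline passes

    def test_voxelwise_oracle(self, rng):
        for _ in range(10):
            grid, _, sa = random_fixture(rng)
            dm = disconnection_map(grid, sa)
            hits = [any(grid.mask[tuple(v)] for v in s)
                    for s in sa.streamlines]
            for v in map(tuple, np.argwhere(np.ones(grid.shape))):
                through = [i for i, s in enumerate(sa.streamlines)
                           if any((np.asarray(v) == p).all() for p in
                                  np.unique(s, axis=0))]
                if not through:
                    assert dm[v] == 0.0
                else:
                    expect = 100.0 * sum(hits[i] for i in through) \
                        / len(through)
                    assert dm[v] == pytest.approx(expect)


class TestSSPL:
    def _chain(self):
        """Three parcels A-B-C with single-streamline edges."""
        shape = (9, 3, 3)
        labels = np.zeros(shape, dtype=int)
        labels[0], labels[4], labels[8] = 1, 2, 3
        atlas = ParcelAtlas(labels=labels, names={1: "A", 2: "B", 3: "C"})
        ab = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0]])
        bc = np.array([[4, 0, 0], [6, 0, 0], [8, 0, 0]])
        sa = StreamlineAtlas(streamlines=[ab, bc],
                             tract_labels=["ab", "bc"], shape=shape)
        return atlas, sa, shape

    def test_no_lesion_zero_delta(self):
        atlas, sa, shape = self._chain()
        g = VoxelGrid(mask=np.zeros(shape), voxel_size=(1, 1, 1))
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert sspl_delta(atlas, sa, g, pair) == 0.0

    def test_severed_edge_is_inf(self):
        atlas, sa, shape = self._chain()
        m = np.zeros(shape)
        m[2, 0, 0] = 1                   # cuts the only A-B streamline
        g = VoxelGrid(mask=m, voxel_size=(1, 1, 1))
        assert math.isinf(sspl_delta(atlas, sa, g, ("A", "B")))

    def test_unreachable_intact_pair_errors(self):
        atlas, sa, shape = self._chain()
        labels = atlas.labels.copy()
        labels[0, 2, 2] = 4
        atlas2 = ParcelAtlas(labels=labels,
                             names={1: "A", 2: "B", 3: "C", 4: "D"})
        g = VoxelGrid(mask=np.zeros(shape), voxel_size=(1, 1, 1))
        with pytest.raises(ValueError, match="unreachable"):
            sspl_delta(atlas2, sa, g, ("A", "D"))

    def test_bfs_matches_floyd_warshall(self, rng):
        from strokebeta.lesions import _parcel_graph

        for _ in range(20):
            grid, atlas, sa = random_fixture(rng, n_parcels=5, n_streams=40)
            for lesioned in (None, grid):
                g = _parcel_graph(atlas, sa, lesioned)
                ids = sorted(atlas.names)
                adj = np.zeros((len(ids), len(ids)))
                for a, b in g.edges:
                    ia, ib = ids.index(a), ids.index(b)
                    adj[ia, ib] = adj[ib, ia] = 1
                dist = floyd_warshall(adj, unweighted=True)
                import networkx as nx

                for i, a in enumerate(ids):
                    for j, b in enumerate(ids):
                        try:
                            d = nx.shortest_path_length(g, a, b)
                        except nx.NetworkXNoPath:
                            d = np.inf
                        assert d == dist[i, j]


class TestFlipSmooth:
    def test_double_flip_identity(self, lesion_fixture):
        _, _, grid = lesion_fixture
        once = flip_and_smooth(grid, fwhm_mm=0, flip_axis=0, binarize=True)
        twice = flip_and_smooth(once, fwhm_mm=0, flip_axis=0, binarize=True)
        np.testing.assert_array_equal(twice.mask, grid.mask)

    def test_zero_fwhm_unchanged(self, lesion_fixture):
        _, _, grid = lesion_fixture
        out = flip_and_smooth(grid, fwhm_mm=0)
        np.testing.assert_allclose(out, grid.mask.astype(float))

    def test_symmetric_mask_flip_invariant(self):
        m = np.zeros((6, 4, 4))
        m[2:4] = 1                        # symmetric about axis-0 midline
        g = VoxelGrid(mask=m, voxel_size=(1, 1, 1))
        out = flip_and_smooth(g, fwhm_mm=2.0, flip_axis=0)
        np.testing.assert_allclose(out, flip_and_smooth(g, fwhm_mm=2.0))


class TestMonotonicityAndMeans:
    def test_growth_never_decreases_metrics(self, rng):
        grid, atlas, sa = random_fixture(rng)
        bigger = VoxelGrid(
            mask=np.clip(grid.mask + (rng.random(grid.shape) < 0.15), 0, 1),
            voxel_size=grid.voxel_size)
        assert lesion_volume(bigger) >= lesion_volume(grid)
        for name in atlas.names.values():
            assert roi_damage(bigger, atlas, name) >= \
                roi_damage(grid, atlas, name)
        for tract in sa.tracts:
            assert tract_disconnection(bigger, sa, tract) >= \
                tract_disconnection(grid, sa, tract)
        assert (disconnection_map(bigger, sa)
                >= disconnection_map(grid, sa) - 1e-12).all()

    def test_projection_commissural_means(self, lesion_fixture):
        atlas, sa, grid = lesion_fixture
        sf = extract_structural_features(grid, atlas, sa)
        assert sf.projection_mean == pytest.approx(np.mean(
            [sf.tract_disconnection[t] for t in PROJECTION_TRACTS]))
        assert sf.commissural_mean == pytest.approx(np.mean(
            [sf.tract_disconnection[t] for t in COMMISSURAL_TRACTS]))
        for v in sf.roi_damage.values():
            assert 0.0 <= v <= 100.0
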