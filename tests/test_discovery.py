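"""ICA decomposition, clade clustering, thresholding and merging."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.cluster import AgglomerativeClustering

from wellnets import discovery
from wellnets.types import RhoSeries


def _planted_rho_series(n_sources=5, grid=(8, 8, 8), T=60, seed=0):
    """Low-rank rho field: product of known maps and timecourses + tiny noise."""
    rng = np.random.default_rng(seed)
    nvox = int(np.prod(grid))
    maps = rng.standard_normal((n_sources, nvox))
    tcs = rng.standard_normal((T, n_sources))
    X = (tcs @ maps).T + 0.01 * rng.standard_normal((nvox, T))
    return RhoSeries(X.reshape(*grid, T), np.ones(grid, bool))


def test_decompose_reconstructs_low_rank_input():
    rho = _planted_rho_series()
    dec = discovery.decompose(rho, 5, seed=0)
    X = np.nan_to_num(rho.masked_matrix())
    recon = discovery.reconstruct(dec)
    resid = X - recon
    frac = 1.0 - resid.var() / X.var()
    assert frac >= 0.90


def test_decompose_maps_standardised():
    rho = _planted_rho_series(seed=1)
    dec = discovery.decompose(rho, 5, seed=0)
    assert np.allclose(dec.maps.mean(axis=1), 0.0, atol=1e-8)
    assert np.allclose(dec.maps.std(axis=1), 1.0, atol=1e-8)
    # sign convention: largest-|loading| positive
    peaks = dec.maps[np.arange(5), np.abs(dec.maps).argmax(axis=1)]
    assert np.all(peaks > 0)


def test_decompose_seed_determinism():
    rho = _planted_rho_series(seed=2)
    a = discovery.decompose(rho, 5, seed=3)
    b = discovery.decompose(rho, 5, seed=3)
    assert np.array_equal(a.maps, b.maps)
    assert np.array_equal(a.timecourses, b.timecourses)


def test_decompose_requires_more_timepoints_than_components():
    rho = _planted_rho_series(T=10)
    with pytest.raises(ValueError):
        discovery.decompose(rho, 10, seed=0)


# ---------------------------------------------------------------------------
# clade clustering


def _decomposition_with_timecourses(tcs):
    k = tcs.shape[1]
    maps = np.random.default_rng(0).standard_normal((k, 64))
    return discovery.ICDecomposition(
        maps=maps,
        timecourses=tcs,
        mask=np.ones((4, 4, 4), bool),
        offset=np.zeros(tcs.shape[0]),
        seed=0,
    )


def test_duplicated_timecourses_co_clustered():
    rng = np.random.default_rng(1)
    base = rng.standard_normal(40)
    tcs = np.column_stack([base, base + 1e-9, rng.standard_normal(40) + 10])
    dec = _decomposition_with_timecourses(tcs)
    part = discovery.cluster_timecourses(dec, 2)
    assert part.clade_of[0] == part.clade_of[1]
    assert part.clade_of[2] != part.clade_of[0]


def test_two_group_structure_matches_independent_implementation():
    rng = np.random.default_rng(2)
    g1 = rng.standard_normal(30)
    g2 = rng.standard_normal(30) + 8.0
    tcs = np.column_stack([g1 + 0.01 * rng.standard_normal(30) for _ in range(3)]
                          + [g2 + 0.01 * rng.standard_normal(30) for _ in range(3)])
    dec = _decomposition_with_timecourses(tcs)
    part = discovery.cluster_timecourses(dec, 2)
    # independent oracle: sklearn agglomerative clustering with Ward linkage
    oracle = AgglomerativeClustering(n_clusters=2, linkage="ward").fit(tcs.T)
    a, b = part.clade_of, oracle.labels_
    same = (a[:, None] == a[None, :]) == (b[:, None] == b[None, :])
    assert same.all()


def test_cut_at_n_components_gives_singletons():
    rng = np.random.default_rng(3)
    tcs = rng.standard_normal((20, 6))
    dec = _decomposition_with_timecourses(tcs)
    part = discovery.cluster_timecourses(dec, 6)
    assert part.n_clades == 6
    assert len(set(part.clade_of.tolist())) == 6


# ---------------------------------------------------------------------------
# GMM thresholding


def test_gmm_threshold_recovers_bimodal_signal():
    rng = np.random.default_rng(4)
    grid = (10, 10, 10)
    vol = rng.standard_normal(grid)
    signal = np.zeros(grid, bool)
    signal.ravel()[rng.choice(1000, 100, replace=False)] = True
    vol[signal] = 6.0 + rng.standard_normal(100)
    tm = discovery.gmm_threshold(vol, seed=0)
    recovered = tm.voxels[signal].mean()
    false_pos = tm.voxels[~signal].mean()
    assert recovered >= 0.95
    assert false_pos <= 0.02


def test_gmm_threshold_shift_invariance():
    rng = np.random.default_rng(5)
    vol = rng.standard_normal((8, 8, 8))
    vol[:2] += 5.0
    a = discovery.gmm_threshold(vol, seed=1)
    b = discovery.gmm_threshold(vol + 17.0, seed=1)
    assert np.array_equal(a.voxels, b.voxels)


def test_gmm_threshold_rejects_constant_map():
    with pytest.raises(ValueError):
        discovery.gmm_threshold(np.zeros((4, 4, 4)), seed=0)


# ---------------------------------------------------------------------------
# cluster size filter


def _blob(grid, origin, size_xyz):
    m = np.zeros(grid, bool)
    x, y, z = origin
    dx, dy, dz = size_xyz
    m[x : x + dx, y : y + dy, z : z + dz] = True
    return m


def test_exactly_min_size_cluster_removed():
    m = _blob((10, 10, 10), (0, 0, 0), (2, 5, 5))  # exactly 50 voxels
    out = discovery.cluster_size_filter(m, 50)
    assert out.n_voxels == 0


def test_min_size_plus_one_retained():
    m = _blob((10, 10, 10), (0, 0, 0), (2, 5, 5))
    m[3, 0, 0] = False  # keep it one cluster of 50... adjust to 51 instead
    m = _blob((10, 10, 10), (0, 0, 0), (2, 5, 5))
    m[2, 0, 0] = True  # 51 voxels, face-connected
    out = discovery.cluster_size_filter(m, 50)
    assert out.n_voxels == 51
    assert out.cluster_sizes == [51]


def test_two_clusters_filtered_against_flood_fill_oracle():
    grid = (12, 12, 12)
    big = _blob(grid, (0, 0, 0), (4, 4, 4))  # 64 voxels
    small = _blob(grid, (8, 8, 7), (4, 2, 5))  # 40 voxels, disconnected
    out = discovery.cluster_size_filter(big | small, 50)
    # flood-fill oracle: component sizes by BFS over the 26-neighbourhood
    sizes = _flood_fill_sizes(big | small)
    assert sorted(sizes) == [40, 64]
    assert out.cluster_sizes == [64]
    assert np.array_equal(out.voxels, big)


def _flood_fill_sizes(m):
    m = m.copy()
    sizes = []
    while m.any():
        seed_idx = tuple(np.argwhere(m)[0])
        stack, comp = [seed_idx], set()
        m[seed_idx] = False
        comp.add(seed_idx)
        while stack:
            x, y, z = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        p = (x + dx, y + dy, z + dz)
                        if all(0 <= c < s for c, s in zip(p, m.shape)) and m[p]:
                            m[p] = False
                            comp.add(p)
                            stack.append(p)
        sizes.append(len(comp))
    return sizes


@pytest.mark.parametrize("conn, expected_joined", [(6, False), (26, True)])
def test_connectivity_rule_controls_corner_joins(conn, expected_joined):
    m = np.zeros((6, 6, 6), bool)
    m[0:2, 0:2, 0:2] = True  # 8 voxels
    m[2, 2, 2] = True  # corner-touching voxel
    out = discovery.cluster_size_filter(m, 0, connectivity=conn)
    assert (9 in out.cluster_sizes) == expected_joined


# ---------------------------------------------------------------------------
# clade merging


def test_merge_single_map_is_identity():
    grid = (5, 5, 5)
    vox = _blob(grid, (0, 0, 0), (2, 2, 2))
    load = np.random.default_rng(6).standard_normal(grid)
    tm = discovery.ThresholdedMap(vox, 0.5, [8])
    merged = discovery.merge_clade([tm], [load])
    assert np.array_equal(merged[vox], load[vox])
    assert np.all(merged[~vox] == 0.0)


def test_merge_disjoint_maps_is_union():
    grid = (6, 6, 6)
    a = _blob(grid, (0, 0, 0), (2, 2, 2))
    b = _blob(grid, (4, 4, 4), (2, 2, 2))
    la = np.ones(grid) * 2.0
    lb = np.ones(grid) * 4.0
    merged = discovery.merge_clade(
        [discovery.ThresholdedMap(a, 0.5, [8]), discovery.ThresholdedMap(b, 0.5, [8])],
        [la, lb],
    )
    assert np.all(merged[a] == 2.0)
    assert np.all(merged[b] == 4.0)


def test_merge_overlap_takes_nonzero_mean():
    grid = (4, 4, 4)
    a = _blob(grid, (0, 0, 0), (2, 2, 2))
    merged = discovery.merge_clade(
        [discovery.ThresholdedMap(a, 0.5, [8]), discovery.ThresholdedMap(a, 0.5, [8])],
        [np.full(grid, 2.0), np.full(grid, 4.0)],
    )
    assert np.all(merged[a] == 3.0)


def test_merge_empty_clade_raises():
    with pytest.raises(ValueError):
        discovery.merge_clade([], [])
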