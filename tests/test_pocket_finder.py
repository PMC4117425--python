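import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexsite import DetectionConfig
from flexsite.pocket_finder import (
    Site,
    cluster_sites,
    filter_supported_points,
    rank_sites,
    site_volume,
)

from helpers import brute_force_neighbor_filter, union_find_clusters


def _block(n, spacing=0.35, origin=(0.0, 0.0, 0.0)):
    ax = spacing * np.arange(n)
    g = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1) + np.asarray(origin)


def test_lone_point_removed_and_dense_block_kept(det_cfg):
    assert len(filter_supported_points(np.zeros((1, 3)), det_cfg)) == 0
    block = _block(5)
    kept = filter_supported_points(block, det_cfg)
    # interior points have 5x5x5-neighbourhoods well above nthresh
    assert len(kept) >= 27
    assert len(kept) <= len(block)


@settings(deadline=None, derandomize=True, max_examples=10)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_support_filter_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 6, size=(60, 3))
    cfg = DetectionConfig()
    got = filter_supported_points(pts, cfg)
    expected = brute_force_neighbor_filter(pts, cfg.neighbor_radius, cfg.nthresh)
    assert np.array_equal(np.sort(got, axis=0), np.sort(expected, axis=0))


def test_cluster_mingroup_and_joining(det_cfg):
    """6 mutually-close points: below mingroup, no site.  Two 20-point
    blobs: separate at 6 A closest distance, joined at 4 A."""
    six = np.random.default_rng(1).normal(scale=0.4, size=(6, 3))
    assert cluster_sites(six, det_cfg) == []

    blob = _block(3, spacing=0.5)  # 27 points, extent ~1 A
    far = blob + np.array([blob[:, 0].max() + 6.0, 0, 0])
    assert len(cluster_sites(np.vstack([blob, far]), det_cfg)) == 2
    near = blob + np.array([blob[:, 0].max() + 4.0, 0, 0])
    assert len(cluster_sites(np.vstack([blob, near]), det_cfg)) == 1


@settings(deadline=None, derandomize=True, max_examples=5)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_clustering_matches_union_find(seed):
    """Cluster memberships equal an explicit union-find on <=500 points."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 40, size=(300, 3))
    cfg = DetectionConfig(mingroup=1)
    got = cluster_sites(pts, cfg)
    got_sets = set()
    index = {tuple(np.round(p, 9)): i for i, p in enumerate(pts)}
    for s in got:
        got_sets.add(frozenset(index[tuple(np.round(p, 9))] for p in s.points))
    expected = set(union_find_clusters(pts, cfg.dthresh))
    assert got_sets == expected


def test_point_count_conserved(det_cfg):
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 25, size=(200, 3))
    sites = cluster_sites(pts, det_cfg)
    kept = sum(s.n for s in sites)
    assert kept <= len(pts)
    # discarded clusters are all below mingroup
    all_clusters = cluster_sites(pts, DetectionConfig(mingroup=1))
    assert sum(s.n for s in all_clusters) == len(pts)
    assert kept == sum(s.n for s in all_clusters if s.n >= det_cfg.mingroup)


def test_rank_sites_top_five_and_stability(det_cfg):
    rng = np.random.default_rng(4)
    sites = []
    for k, n in enumerate([40, 35, 30, 25, 20, 15, 10]):
        pts = rng.normal(size=(n, 3)) + 100 * k
        sites.append(Site(site_id=k + 1, points=pts, n=n, volume=float(n)))
    top = rank_sites(list(sites), det_cfg)
    assert [s.n for s in top] == [40, 35, 30, 25, 20]
    assert [s.rank for s in top] == [1, 2, 3, 4, 5]
    single = rank_sites([sites[0]], det_cfg)
    assert single[0].rank == 1
    # equal-n sites order deterministically (volume, then centroid)
    a = Site(site_id=1, points=np.zeros((5, 3)), n=5, volume=10.0)
    b = Site(site_id=2, points=np.ones((5, 3)), n=5, volume=20.0)
    assert [s.site_id for s in rank_sites([a, b], det_cfg)] == [2, 1]
    assert [s.site_id for s in rank_sites([b, a], det_cfg)] == [2, 1]


def test_site_volume_cell_counting(det_cfg):
    one = Site(site_id=1, points=np.array([[0.0, 0.0, 0.0]]), n=1)
    assert site_volume(one, det_cfg) == pytest.approx(0.35**3)
    block = Site(site_id=2, points=_block(10), n=1000)
    assert site_volume(block, det_cfg) == pytest.approx(1000 * 0.35**3)


def test_volume_additive_disjoint(det_cfg):
    a = Site(site_id=1, points=_block(4), n=64)
    b = Site(site_id=2, points=_block(4, origin=(30.0, 0, 0)), n=64)
    both = Site(site_id=3, points=np.vstack([a.points, b.points]), n=128)
    assert site_volume(both, det_cfg) == pytest.approx(
        site_volume(a, det_cfg) + site_volume(b, det_cfg)
    )


def test_spherical_cavity_volume(sphere5_detection):
    """Detected cavity volume of the 5 A spherical void within 15% of
    (4/3) pi r^3."""
    _, sites = sphere5_detection
    assert len(sites) == 1
    truth = 4.0 / 3.0 * np.pi * 125.0
    assert abs(sites[0].volume - truth) / truth <= 0.15


def test_oversized_flagging(det_cfg):
    s = Site(site_id=1, points=_block(2), n=8, volume=900.0)
    s.oversized = s.volume > 800.0
    assert s.oversized
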