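import numpy as np
import pytest

from flexsite import DetectionConfig, FixtureSpec, generate
from flexsite.site_grid import (
    LJ_PARAMS,
    PROBE_EPS,
    PROBE_RMIN2,
    MemoryBudgetError,
    build_grid,
    enclosure_at_points,
    enclosure_field,
    fibonacci_sphere,
    mark_site_points,
    vdw_energy_field,
)
from flexsite.structure_io import PreparedStructure

from helpers import brute_force_inside, dense_ray_enclosure


def _atoms(coords, element="C"):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return PreparedStructure(
        element=np.full(n, element, dtype="U2"),
        coords=coords,
        occupancy=np.ones(n),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ZQX", dtype="U5"),
        chain_id=np.full(n, "A", dtype="U4"),
        atom_name=np.full(n, element, dtype="U6"),
        is_het=np.zeros(n, dtype=bool),
    )


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(grid_spacing=-0.1)
    with pytest.raises(ValueError):
        DetectionConfig(enclosure_min=1.2)
    with pytest.raises(ValueError):
        DetectionConfig(nthresh=0)


def test_grid_margin_and_inside_flag():
    """Single atom: points within its vdW radius flagged, margin fully
    covers the atom + 8 A, far corners stay outside."""
    cfg = DetectionConfig(grid_spacing=0.5)
    s = _atoms([[0.0, 0.0, 0.0]])
    g = build_grid(s, cfg)
    assert np.all(g.origin <= -cfg.margin + 1e-9)
    pts = g.point_coords(np.ones(g.dims, dtype=bool))
    r = np.linalg.norm(pts, axis=1)
    inside = g.inside_receptor.ravel()
    assert np.all(r[inside] <= 1.7 + 1e-9)
    assert not inside[r > 1.7 + cfg.grid_spacing].any()


def test_inside_matches_brute_force():
    rng = np.random.default_rng(0)
    coords = rng.normal(scale=2.0, size=(10, 3))
    cfg = DetectionConfig(grid_spacing=0.7)
    s = _atoms(coords)
    g = build_grid(s, cfg)
    pts = g.point_coords(np.ones(g.dims, dtype=bool))
    expected = brute_force_inside(pts, coords, np.full(10, 1.7))
    assert np.array_equal(g.inside_receptor.ravel(), expected)


def test_memory_budget_error():
    s = _atoms([[0.0, 0.0, 0.0], [200.0, 200.0, 200.0]])
    with pytest.raises(MemoryBudgetError, match="grid_spacing"):
        build_grid(s, DetectionConfig(grid_spacing=0.35, max_points=1000))


def test_vdw_energy_reference_values():
    """Beyond cutoff: zero.  At the pair minimum: -eps.  Midway between two
    atoms: the sum of the two pair terms."""
    cfg = DetectionConfig(grid_spacing=0.5)
    rm = PROBE_RMIN2 + LJ_PARAMS["C"][0]
    eps = np.sqrt(PROBE_EPS * LJ_PARAMS["C"][1])

    s = _atoms([[0.0, 0.0, 0.0]])
    g = vdw_energy_field(build_grid(s, cfg), s, cfg)
    pts = g.point_coords(np.ones(g.dims, dtype=bool))
    e = g.vdw_energy.ravel()
    r = np.linalg.norm(pts, axis=1)
    assert np.all(e[r > cfg.vdw_cutoff + 1e-6] == 0.0)
    at_min = np.isclose(r, rm, atol=1e-9)
    if at_min.any():
        assert np.allclose(e[at_min], -eps, atol=1e-9)
    # grid point on the axis at exactly rm: place atoms so it exists
    s2 = _atoms([[-rm, 0.0, 0.0], [rm, 0.0, 0.0]])
    g2 = vdw_energy_field(build_grid(s2, cfg), s2, cfg)
    idx = g2.index_of(np.array([[0.0, 0.0, 0.0]]))[0]
    # midpoint: two pair terms at distance rm each
    assert g2.vdw_energy[tuple(idx)] == pytest.approx(-2 * eps, rel=1e-9)
    assert np.isinf(g2.vdw_energy[g2.inside_receptor]).all()


def test_enclosure_closed_shell_and_isolated_point():
    s, _ = generate(FixtureSpec(kind="spherical_cavity", radius=5.0))
    cfg = DetectionConfig()
    assert enclosure_at_points(np.zeros((1, 3)), s, cfg)[0] == 1.0
    far = s.coords.max(axis=0) + 50.0
    assert enclosure_at_points(far[None, :], s, cfg)[0] == 0.0


def test_enclosure_rotation_invariance(hemi5, det_cfg):
    """Rigid rotation of the structure changes enclosure by no more than
    the ray-set discretisation tolerance."""
    s, truth = hemi5
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [31.0, -17.0, 59.0], degrees=True).as_matrix()
    s2 = _atoms(s.coords[s.heavy_mask] @ R.T, element="C")
    p = truth.mouth_center
    e1 = enclosure_at_points(p[None, :], s, det_cfg)[0]
    e2 = enclosure_at_points((R @ p)[None, :], s2, det_cfg)[0]
    assert abs(e1 - e2) <= 0.02


def test_march_field_consistent_with_analytic(sphere5, sphere5_detection, det_cfg):
    """The marching enclosure field agrees with exact ray-sphere values at
    sampled site points."""
    s, _ = sphere5
    grid, sites = sphere5_detection
    pts = sites[0].points[:: max(1, sites[0].n // 20)]
    idx = grid.index_of(pts)
    field_vals = grid.enclosure_fraction[idx[:, 0], idx[:, 1], idx[:, 2]]
    exact = enclosure_at_points(pts, s, det_cfg)
    assert np.abs(field_vals - exact).max() <= 0.05


def test_mouth_enclosure_vs_dense_oracle(hemi5, det_cfg):
    s, truth = hemi5
    impl = enclosure_at_points(truth.mouth_center[None, :], s, det_cfg)[0]
    oracle = dense_ray_enclosure(truth.mouth_center, s, n_rays=200_000)
    assert impl == pytest.approx(oracle, abs=0.02)


def test_site_point_predicates(gated_detection, det_cfg):
    """Marked site points exactly satisfy outside & enclosed & favourable."""
    grid, _ = gated_detection
    expected = (
        (~grid.inside_receptor)
        & (grid.enclosure_fraction >= det_cfg.enclosure_min)
        & (grid.vdw_energy <= -det_cfg.maxvdw)
    )
    assert np.array_equal(grid.is_site_point, expected)


def test_maxvdw_monotonicity(gated, det_cfg):
    """Raising maxvdw shrinks the site-point set (set inclusion)."""
    s, _ = gated
    from dataclasses import replace

    g = build_grid(s, det_cfg)
    vdw_energy_field(g, s, det_cfg)
    enclosure_field(g, s, det_cfg)
    mark_site_points(g, det_cfg)
    base = g.is_site_point.copy()
    stricter = replace(det_cfg, maxvdw=1.5)
    mark_site_points(g, stricter)
    assert not (g.is_site_point & ~base).any()
    assert g.is_site_point.sum() <= base.sum()


def test_phobic_philic_reference_values(det_cfg):
    """Pure-carbon surroundings: philic 0; empty surroundings: both 0;
    mixed: direct kernel-sum oracle."""
    from helpers import kernel_sum
    from flexsite.site_grid import (
        PHILIC_REFERENCE_MEAN,
        PHOBIC_REFERENCE_MEAN,
        phobic_philic_fields,
    )

    coords = np.array([[2.0, 0, 0], [0, 3.0, 0], [-2.5, 0, 0], [0, -4.0, 0]])
    elements = np.array(["C", "C", "O", "N"])
    s = _atoms(coords)
    s.element = elements
    s.atom_name = elements.astype("U6")
    cfg = DetectionConfig(grid_spacing=0.5)
    g = phobic_philic_fields(build_grid(s, cfg), s, cfg)
    idx = g.index_of(np.array([[0.0, 0.0, 0.0]]))[0]
    phob = g.phobic_potential[tuple(idx)] * PHOBIC_REFERENCE_MEAN
    phil = g.philic_potential[tuple(idx)] * PHILIC_REFERENCE_MEAN
    assert phob == pytest.approx(kernel_sum([0, 0, 0], coords[:2], np.ones(2), 6.0), rel=1e-6)
    assert phil == pytest.approx(kernel_sum([0, 0, 0], coords[2:], np.ones(2), 6.0), rel=1e-6)
    # far corner: nothing within 6 A
    corner = g.index_of(np.array([g.origin]))[0]
    assert g.phobic_potential[tuple(corner)] == 0.0
    assert g.philic_potential[tuple(corner)] == 0.0


def test_fibonacci_rays_unit_and_balanced():
    rays = fibonacci_sphere(110)
    assert np.allclose(np.linalg.norm(rays, axis=1), 1.0)
    assert np.abs(rays.mean(axis=0)).max() < 0.02
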