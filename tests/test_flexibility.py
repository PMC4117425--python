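import numpy as np
import pytest

from flexsite import FixtureSpec, generate
from flexsite.flexibility import (
    FlexConfig,
    FlexModel,
    Pose,
    Probe,
    _ReceptorContext,
    backbone_rmsd,
    dock_probe,
    flexible_result,
    repack_side_chains,
)
from flexsite.pocket_finder import Site


@pytest.fixture(scope="module")
def naphthalene():
    return Probe.from_name("naphthalene")


@pytest.fixture(scope="module")
def tsn():
    return Probe.from_name("TSN")


def test_naphthalene_geometry(naphthalene):
    """Rigid, 10 carbons, planar within tolerance."""
    p = naphthalene
    assert len(p.elements) == 10
    assert set(p.elements) == {"C"}
    assert p.rotatable_bonds == []
    # planarity: smallest singular value of the centred coordinates ~ 0
    sv = np.linalg.svd(p.coords - p.coords.mean(0), compute_uv=False)
    assert sv[-1] < 0.1
    assert p.molecular_weight == pytest.approx(128.2, abs=0.5)


def test_tsn_geometry(tsn):
    """~363 Da with four rotatable substituents."""
    assert tsn.molecular_weight == pytest.approx(363.0, abs=2.0)
    assert len(tsn.rotatable_bonds) == 4
    assert len(tsn.elements) == 27  # heavy atoms


def test_probe_sdf_export(tmp_path, naphthalene):
    path = tmp_path / "naphthalene.sdf"
    naphthalene.to_sdf(path)
    text = path.read_text()
    assert "naphthalene" in text and "END" in text


def test_dock_finds_pocket_and_is_deterministic(gated, gated_pocket_site, naphthalene):
    s, _ = gated
    site = gated_pocket_site
    cfg = FlexConfig(seed=7)
    ctx = _ReceptorContext(s, cfg)
    poses = dock_probe(s, site, naphthalene, cfg, context=ctx)
    assert poses, "pocket should admit naphthalene"
    assert poses[0].energy < 0
    # best pose sits at the pocket, near the site centroid
    anchor = site.points.mean(0)
    assert np.linalg.norm(poses[0].coords.mean(0) - anchor) < 4.0
    # energies sorted ascending
    energies = [p.energy for p in poses]
    assert energies == sorted(energies)
    # identical rerun with the same seed
    again = dock_probe(s, site, naphthalene, cfg, context=ctx)
    assert len(again) == len(poses)
    assert np.array_equal(again[0].coords, poses[0].coords)


def test_tiny_cavity_rejects_probe(naphthalene):
    """A 2 A cavity cannot hold naphthalene: no admissible pose."""
    s, _ = generate(FixtureSpec(kind="spherical_cavity", radius=2.0))
    fake = Site(site_id=1, points=np.zeros((1, 3)), n=1)
    poses = dock_probe(s, fake, naphthalene, FlexConfig())
    assert poses == []


def test_repack_opens_gate_and_preserves_backbone(gated, gated_pocket_site, naphthalene):
    s, truth = gated
    cfg = FlexConfig(seed=0, backbone_relax=False)
    pose = dock_probe(s, gated_pocket_site, naphthalene, cfg)[0]
    variant, moved, ok = repack_side_chains(s, pose, cfg)
    assert ok
    gate = truth.gate
    flips = {(m["res_name"], m["res_id"]) for m in moved}
    assert (gate["res_name"], gate["res_id"]) in flips
    trp = next(m for m in moved if m["res_id"] == gate["res_id"])
    assert np.allclose(trp["chis_to"], gate["open_chis"], atol=1.0)
    # side-chain-only mode leaves every backbone atom untouched
    assert backbone_rmsd(s, variant) == 0.0
    bb = np.isin(s.atom_name, ("N", "CA", "C", "O"))
    assert np.allclose(s.coords[bb], variant.coords[bb])


def test_repack_noop_far_from_residues(gated, naphthalene):
    """A probe in open solvent with no residues in range changes nothing."""
    s, _ = gated
    cfg = FlexConfig()
    far = Pose(probe="naphthalene",
               coords=naphthalene.coords + np.array([60.0, 60.0, 60.0]),
               energy=0.0)
    variant, moved, ok = repack_side_chains(s, far, cfg)
    assert ok and moved == []
    assert np.array_equal(variant.coords, s.coords)


def _model(score, volume):
    site = Site(site_id=1, points=np.zeros((3, 3)), n=3, volume=volume)
    from flexsite.descriptors import SiteDescriptors

    d = SiteDescriptors(e=0.5, n=3, V=volume, h=0.0, p=0.0)
    d.dscore = score
    d.dscore_plus = score
    site.descriptors = d
    return FlexModel(receptor=None, pose=Pose("TSN", np.zeros((1, 3)), -1.0),
                     pose_energy=-1.0, moved_residues=[], site=site)


def test_flexible_result_argmax_and_ties():
    models = [_model(1.8, 200), _model(2.1, 240), _model(1.9, 150), _model(2.0, 300)]
    assert flexible_result(models) == (2.1, 240)
    assert flexible_result([_model(1.5, 120)]) == (1.5, 120)
    tie = [_model(2.0, 200), _model(2.0, 300)]
    assert flexible_result(tie) == (2.0, 300)
    with pytest.raises(ValueError):
        flexible_result([])


def test_flex_config_contract_defaults():
    cfg = FlexConfig()
    assert cfg.outer_box == 25.0
    assert cfg.n_naph_poses_kept == 2
    assert cfg.n_models_scored == 4
    assert cfg.min_models_generated == 10
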