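import numpy as np
import pytest

from flexsite import FixtureSpec, generate
from flexsite.decision import (
    DecisionConfig,
    DruggabilityRecord,
    annotate_interfaces,
    classify,
    rigid_gate,
    run_pipeline,
)
from flexsite.flexibility import FlexModel, Pose
from flexsite.pocket_finder import Site


def _record(rigid_dp, rigid_v, e_pct=80.0, flex=None, chain=150):
    r = DruggabilityRecord(
        structure_id="x", site_id=1, rank=1,
        rigid_dscore_plus=rigid_dp, rigid_volume=rigid_v,
        rigid_enclosure_percent=e_pct, chain_residues=chain,
    )
    if flex is not None:
        r.flexible_dscore_plus, r.flexible_volume = flex
    return r


def test_rigid_gate_strict_threshold():
    assert not rigid_gate(0.9)       # difficult-range score
    assert not rigid_gate(1.3)       # boundary is strict
    assert rigid_gate(1.5)


def test_classify_reference_rows():
    """Published validation rows: a small pocket that opens is druggable
    (not cryptic when the initial volume exceeds 100 A^3); a pocket that
    stays small is difficult; the full cryptic rule fires when every
    branch holds."""
    r = classify(_record(1.5, 112, flex=(2.4, 172)))
    assert r.label == "druggable_flexible"
    r = classify(_record(1.4, 73, flex=(1.4, 72)))
    assert r.label == "difficult"
    r = classify(_record(1.5, 90, e_pct=88.0, flex=(1.9, 200), chain=150))
    assert r.label == "cryptic_druggable"


def test_classify_inconsistent_inputs():
    bad = _record(float("nan"), 100.0, flex=(2.0, 200))
    with pytest.raises(ValueError):
        classify(bad)


def test_cryptic_requires_every_branch():
    base = dict(rigid_dp=1.5, rigid_v=90, e_pct=88.0, flex=(1.9, 200))
    assert classify(_record(**base)).label == "cryptic_druggable"
    assert classify(_record(**{**base, "rigid_v": 101})).label == "druggable_flexible"
    assert classify(_record(**{**base, "e_pct": 97.0})).label == "druggable_flexible"
    assert classify(_record(**base, chain=99)).label == "druggable_flexible"
    assert classify(_record(**{**base, "flex": (1.6, 200)})).label == "difficult"
    assert classify(_record(**{**base, "flex": (1.9, 150)})).label == "difficult"
    # strict-enclosure mode flips the <= 96 boundary case
    cfg = DecisionConfig(cryptic_strict_enclosure=True)
    at_bound = _record(1.5, 90, e_pct=96.0, flex=(1.9, 200))
    assert classify(at_bound, cfg).label == "druggable_flexible"
    assert classify(_record(1.5, 90, e_pct=96.0, flex=(1.9, 200))).label == "cryptic_druggable"


@pytest.mark.parametrize("score", [1.3, 1.69, 1.7])
@pytest.mark.parametrize("volume", [100, 159, 160, 800, 801])
def test_classification_truth_table(score, volume):
    """Exhaustive boundary grid: flexible gate is >= 1.7 and the drug-like
    volume range is inclusive at both ends (160 and 800)."""
    r = classify(_record(1.5, 120, flex=(score, volume)))
    druggable = score >= 1.7 and 160 <= volume <= 800
    if druggable:
        assert r.label in ("druggable_flexible", "cryptic_druggable")
    else:
        assert r.label == "difficult"
    # the same grid on the rigid side controls advancement and oversize
    r2 = classify(_record(score, volume))
    if volume > 800:
        assert r2.label == "oversized_site"
    elif score <= 1.3:
        assert r2.label == "not_advanced"
    else:
        assert r2.label in ("druggable_rigid", "difficult")
        assert r2.rigid_druggable == (160 <= volume <= 800)


def test_annotate_ppi_interface(gated):
    """A TSN pose atom within 2 A of a second protein chain flags the
    pocket as a protein-protein interface."""
    s, _ = gated
    import copy

    s2 = copy.deepcopy(s)
    s2.chain_id = s2.chain_id.copy()
    other = s2.coords[:, 2] < s2.coords[:, 2].mean()
    s2.chain_id[other] = "B"
    target = s2.coords[other][0]
    pose = Pose("TSN", coords=target[None, :] + np.array([[1.8, 0.0, 0.0]]), energy=-1.0)
    model = FlexModel(receptor=None, pose=pose, pose_energy=-1.0, moved_residues=[])
    site = Site(site_id=1, points=s2.coords[~other][:5], n=5)
    rec = _record(1.5, 200)
    annotate_interfaces(rec, s2, [model], site=site)
    assert rec.ppi_interface
    # far pose: no flag
    far = Pose("TSN", coords=np.full((1, 3), 500.0), energy=-1.0)
    rec2 = _record(1.5, 200)
    annotate_interfaces(rec2, s2, [FlexModel(None, far, -1.0, [])], site=site)
    assert not rec2.ppi_interface


def test_annotate_ligand_pocket(gated):
    """Site cells overlapping a removed ligand's vdW envelope set the
    ligand-pocket flag with a positive overlap volume."""
    from flexsite.structure_io import RemovedLigand

    s, _ = gated
    import copy

    s2 = copy.deepcopy(s)
    pts = np.array([[0.0, 0.0, 7.0], [0.35, 0.0, 7.0], [50.0, 50.0, 50.0]])
    site = Site(site_id=1, points=pts, n=3)
    s2.removed_ligands = [
        RemovedLigand(
            name="LIG", chain_id="A", res_id=9, molecular_weight=300.0,
            coords=np.array([[0.0, 0.0, 7.0]]), elements=np.array(["C"]),
        )
    ]
    rec = _record(1.5, 200)
    annotate_interfaces(rec, s2, [], site=site)
    assert rec.ligand_pocket
    assert rec.ligand_overlap_volume > 0
    # isolated monomer with no ligands: both flags false
    rec2 = _record(1.5, 200)
    s2.removed_ligands = []
    annotate_interfaces(rec2, s2, [], site=site)
    assert not rec2.ligand_pocket and not rec2.ppi_interface


def test_pipeline_slab_yields_no_sites():
    s, _ = generate(FixtureSpec(kind="slab"))
    assert run_pipeline("slab", structure=s) == []


def test_pipeline_two_cavities_ranked():
    """Two equal pockets produce two records at ranks 1 and 2."""
    s, truth = generate(FixtureSpec(kind="two_cavity", radius=3.6, apolar_fraction=0.0))
    records = run_pipeline("two_cavity", structure=s)
    assert len(records) == truth.n_cavities == 2
    assert [r.rank for r in records] == [1, 2]
    assert all(r.chain_residues > 100 for r in records)


def test_records_serialise(gated_records):
    from flexsite.decision import records_to_json

    payload = records_to_json(gated_records)
    assert payload and payload[0]["rigid"]["dscore_plus"] > 0
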