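"""Two-stage hydrophobic-probe induced-fit opening of candidate pockets.

Stage 1 docks rigid naphthalene into a detected site and repacks nearby
side chains around the best poses; stage 2 docks a larger tetra-substituted
naphthalene (TSN, ~363 Da: ethyl, propyl and two cyclohexyl substituents)
into the pocket opened by naphthalene, repacks again, and re-scores the
site on each resulting receptor model.  The procedure emulates an
induced-fit docking workflow with a fully specified desk-scale algorithm:
exhaustive rigid-body probe search (translations on a ~1 A lattice of site
points x a seeded uniform rotation set, TSN substituent torsions refined
greedily at 60 degree steps) plus greedy rotamer repacking with an optional
capped local backbone relaxation.

Pose energies are internal (kcal/mol-scale): a clamped attractive
Lennard-Jones sum plus a hydrophobic-contact bonus minus a soft clash
penalty; only their ordering matters, and any net-favourable pose is
admitted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import rotamers as _rot
from .descriptors import ScoreWeights, compute_descriptors, round_reported
from .pocket_finder import Site, find_sites
from .site_grid import (
    DetectionConfig,
    LJ_PARAMS,
    VDW_RADII,
    DEFAULT_VDW_RADIUS,
    detect_fields,
)
from .structure_io import PreparedStructure, Structure

__all__ = [
    "Probe",
    "FlexConfig",
    "Pose",
    "FlexModel",
    "dock_probe",
    "repack_side_chains",
    "induced_fit_cycle",
    "flexible_result",
]


# ---------------------------------------------------------------------------
# probes


NAPHTHALENE_SMILES = "c1ccc2ccccc2c1"
TSN_SMILES = "CCc1cc2cc(CCC)c(C3CCCCC3)cc2c(C4CCCCC4)c1"
_EMBED_SEED = 20140731


@dataclass
class Probe:
    """A docking probe: naphthalene (rigid, planar, 10 carbons) or the
    tetra-substituted naphthalene TSN (four rotatable substituents)."""

    name: str
    elements: np.ndarray          # heavy atoms
    coords: np.ndarray            # (n, 3), centred on the centroid
    rotatable_bonds: list         # [(i, j, moving_index_array), ...]
    molecular_weight: float

    @classmethod
    def from_name(cls, name: str) -> "Probe":
        from rdkit import Chem
        from rdkit.Chem import AllChem, Descriptors

        smiles = {"naphthalene": NAPHTHALENE_SMILES, "TSN": TSN_SMILES}[name]
        mol = Chem.MolFromSmiles(smiles)
        mol = Chem.AddHs(mol)
        AllChem.EmbedMolecule(mol, randomSeed=_EMBED_SEED)
        AllChem.MMFFOptimizeMolecule(mol)
        mw = Descriptors.MolWt(mol)
        mol = Chem.RemoveHs(mol)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        elements = np.array(
            [a.GetSymbol().upper() for a in mol.GetAtoms()], dtype="U2"
        )
        rotatable = []
        if name == "TSN":
            ri = mol.GetRingInfo()
            for bond in mol.GetBonds():
                a, b = bond.GetBeginAtom(), bond.GetEndAtom()
                if a.GetIsAromatic() != b.GetIsAromatic() and not ri.NumBondRings(
                    bond.GetIdx()
                ):
                    i = a.GetIdx() if a.GetIsAromatic() else b.GetIdx()
                    j = b.GetIdx() if a.GetIsAromatic() else a.GetIdx()
                    moving = _distal_atoms(mol, i, j)
                    rotatable.append((i, j, np.array(sorted(moving), dtype=int)))
        coords = coords - coords.mean(axis=0)
        return cls(
            name=name,
            elements=elements,
            coords=coords,
            rotatable_bonds=rotatable,
            molecular_weight=float(mw),
        )

    def to_sdf(self, path) -> None:
        from rdkit import Chem
        from rdkit.Chem import AllChem

        smiles = {"naphthalene": NAPHTHALENE_SMILES, "TSN": TSN_SMILES}[self.name]
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        AllChem.EmbedMolecule(mol, randomSeed=_EMBED_SEED)
        AllChem.MMFFOptimizeMolecule(mol)
        with Chem.SDWriter(str(path)) as w:
            mol.SetProp("_Name", self.name)
            w.write(mol)


def _distal_atoms(mol, i: int, j: int) -> set:
    """Atom indices on the j-side of bond i-j."""
    seen = {i, j}
    stack = [j]
    out = set()
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            k = nb.GetIdx()
            if k not in seen:
                seen.add(k)
                out.add(k)
                stack.append(k)
    return out


# ---------------------------------------------------------------------------
# configuration / results


@dataclass(frozen=True)
class FlexConfig:
    """Induced-fit procedure parameters."""

    outer_box: float = 25.0          # A, re-scoring box edge around the anchor
    n_naph_poses_kept: int = 2
    n_models_scored: int = 4
    min_models_generated: int = 10
    clash_distance: float = 0.6      # A of tolerated vdW overlap
    repack_radius: float = 5.0       # A around the probe
    seed: int = 0
    n_orientations: int = 60         # rigid-rotation samples per translation
    translation_spacing: float = 1.0  # A, site-point lattice subsampling
    admission_ceiling: float = 0.0   # poses must score below this
    hydrophobic_bonus: float = 0.05  # kcal/mol per apolar contact
    contact_radius: float = 4.5      # A, hydrophobic contact range
    clash_k: float = 3.0             # kcal/mol/A^2 soft clash stiffness
    backbone_relax: bool = True
    max_backbone_shift: float = 1.5  # A, light-flexibility cap
    max_torsion_poses: int = 8       # TSN poses refined per receptor variant


@dataclass
class Pose:
    probe: str
    coords: np.ndarray
    energy: float


@dataclass
class FlexModel:
    """A repacked receptor variant with its probe pose and re-scored site."""

    receptor: PreparedStructure
    pose: Pose
    pose_energy: float
    moved_residues: list
    site: Site | None = None
    backbone_rmsd: float = 0.0


# ---------------------------------------------------------------------------
# energies


def _pair_tables(elements: np.ndarray):
    rmin2 = np.array([LJ_PARAMS.get(str(e), LJ_PARAMS["C"])[0] for e in elements])
    eps = np.array([LJ_PARAMS.get(str(e), LJ_PARAMS["C"])[1] for e in elements])
    radii = np.array([VDW_RADII.get(str(e), DEFAULT_VDW_RADIUS) for e in elements])
    return rmin2, eps, radii


class _ReceptorContext:
    """Precomputed receptor tables for fast pose scoring."""

    def __init__(self, s: Structure, cfg: FlexConfig):
        self.cfg = cfg
        heavy = s.heavy_mask
        self.heavy_index = np.flatnonzero(heavy)
        self.xyz = s.coords[heavy]
        self.elements = s.element[heavy]
        self.rmin2, self.eps, self.radii = _pair_tables(self.elements)
        from .site_grid import _polarity_classes

        _, _, self.apolar = _polarity_classes(s)
        self.tree = cKDTree(self.xyz)

    def pose_energy(self, probe: Probe, xyz: np.ndarray,
                    exclude: np.ndarray | None = None):
        """(energy, max_overlap) of a probe placement.

        energy = clamped attractive LJ + hydrophobic bonus + soft clash
        penalty; ``exclude`` masks receptor heavy atoms ignored in scoring
        (e.g. the residue being repacked).
        """
        cfg = self.cfg
        p_rmin2, p_eps, p_rad = _pair_tables(probe.elements)
        total = 0.0
        max_overlap = 0.0
        lists = self.tree.query_ball_point(xyz, 8.0)
        for a, nb in enumerate(lists):
            if not nb:
                continue
            nb = np.asarray(nb, dtype=int)
            if exclude is not None:
                nb = nb[~exclude[nb]]
                if len(nb) == 0:
                    continue
            d = np.linalg.norm(self.xyz[nb] - xyz[a], axis=1)
            rm = p_rmin2[a] + self.rmin2[nb]
            ep = np.sqrt(p_eps[a] * self.eps[nb])
            # attractive branch, clamped at the well depth
            dc = np.maximum(d, rm)
            inv6 = (rm / dc) ** 6
            total += float(np.sum(ep * (inv6 * inv6 - 2.0 * inv6)))
            # hydrophobic contact bonus (apolar carbon pairs)
            if probe.elements[a] == "C":
                contact = (d <= cfg.contact_radius) & self.apolar[nb]
                total -= cfg.hydrophobic_bonus * float(contact.sum())
            # soft clash penalty beyond the tolerated overlap
            overlap = (p_rad[a] + self.radii[nb]) - d
            if len(overlap):
                mo = float(overlap.max())
                max_overlap = max(max_overlap, mo)
                excess = np.maximum(0.0, overlap - cfg.clash_distance)
                total += cfg.clash_k * float(np.sum(excess**2)) * 10.0
        return total, max_overlap


# ---------------------------------------------------------------------------
# docking


def _rotation_set(cfg: FlexConfig) -> np.ndarray:
    return Rotation.random(cfg.n_orientations, random_state=cfg.seed).as_matrix()


def _translations(site: Site, cfg: FlexConfig,
                  receptor_com: np.ndarray | None = None) -> np.ndarray:
    """1 A lattice over the site points; when the receptor centre of mass
    is known, outward-shifted copies (2 and 4 A along the local outward
    direction) are added so that a large probe can perch across a pocket
    mouth with its bulk in solvent."""
    h = cfg.translation_spacing
    cells = np.unique(np.rint(site.points / h).astype(int), axis=0) * h
    if receptor_com is None:
        return cells
    u = cells - receptor_com[None, :]
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    u = np.divide(u, norm, out=np.zeros_like(u), where=norm > 1e-9)
    out = np.vstack([cells, cells + 2.0 * u, cells + 4.0 * u])
    return np.unique(np.rint(out / h).astype(int), axis=0) * h


def dock_probe(s: Structure, site: Site, probe: Probe,
               cfg: FlexConfig | None = None,
               context: _ReceptorContext | None = None,
               admit_all: bool = False,
               outward_offsets: bool = False) -> list:
    """Exhaustive rigid-body probe search over the site.

    Translations run over a ``translation_spacing`` lattice of the site
    points, each combined with a seeded quasi-uniform rotation set (TSN
    substituent torsions are refined afterwards, see
    :func:`induced_fit_cycle`).  Poses scoring below the admission ceiling
    are returned sorted by ascending energy; an empty list means the site
    cannot hold the probe.
    """
    cfg = cfg or FlexConfig()
    ctx = context or _ReceptorContext(s, cfg)
    anchor = site.points.mean(axis=0)
    box = cfg.outer_box / 2.0
    poses = []
    rotations = _rotation_set(cfg)
    com = ctx.xyz.mean(axis=0) if outward_offsets else None
    for t in _translations(site, cfg, receptor_com=com):
        if np.any(np.abs(t - anchor) > box):
            continue
        for R in rotations:
            xyz = probe.coords @ R.T + t
            e, _ = ctx.pose_energy(probe, xyz)
            if admit_all or e < cfg.admission_ceiling:
                poses.append(Pose(probe=probe.name, coords=xyz, energy=float(e)))
    poses.sort(key=lambda p: (p.energy, tuple(np.round(p.coords[0], 6))))
    return poses


def _diverse_poses(poses: list, n: int, min_separation: float = 2.0) -> list:
    """Best n poses with pairwise centroid separation >= min_separation
    (falls back to the plain top-n when diversity cannot be met)."""
    kept: list = []
    for p in poses:
        c = p.coords.mean(axis=0)
        if all(np.linalg.norm(c - q.coords.mean(axis=0)) >= min_separation
               for q in kept):
            kept.append(p)
        if len(kept) == n:
            return kept
    kept_ids = {id(p) for p in kept}
    for p in poses:
        if id(p) not in kept_ids:
            kept.append(p)
            kept_ids.add(id(p))
        if len(kept) == n:
            break
    return kept


def _refine_torsions(probe: Probe, pose: Pose, ctx: _ReceptorContext,
                     cfg: FlexConfig) -> Pose:
    """Greedy 60-degree torsion refinement of the TSN substituents."""
    if not probe.rotatable_bonds:
        return pose
    xyz = pose.coords.copy()
    best_e, _ = ctx.pose_energy(probe, xyz)
    for _sweep in range(2):
        for (i, j, moving) in probe.rotatable_bonds:
            axis_origin = xyz[i]
            axis = xyz[j] - xyz[i]
            best_angle = 0.0
            for angle in (0.0, 60.0, 120.0, 180.0, 240.0, 300.0):
                if angle == 0.0:
                    e = best_e
                else:
                    R = _rot._rotation_about_axis(axis, angle)
                    trial = xyz.copy()
                    trial[moving] = (trial[moving] - axis_origin) @ R.T + axis_origin
                    e, _ = ctx.pose_energy(probe, trial)
                if e < best_e - 1e-9:
                    best_e, best_angle = e, angle
            if best_angle != 0.0:
                R = _rot._rotation_about_axis(axis, best_angle)
                xyz[moving] = (xyz[moving] - axis_origin) @ R.T + axis_origin
    return Pose(probe=probe.name, coords=xyz, energy=float(best_e))


# ---------------------------------------------------------------------------
# repacking


def _residues_near(s: Structure, xyz: np.ndarray, radius: float) -> list:
    """(chain, res_id, res_name) of rotatable residues with a heavy atom
    within ``radius`` of any probe atom."""
    tree = cKDTree(xyz)
    heavy = s.heavy_mask & ~s.is_het
    idx = np.flatnonzero(heavy)
    hits = tree.query_ball_point(s.coords[idx], radius, return_length=True)
    out = []
    seen = set()
    for k in idx[hits > 0]:
        key = (str(s.chain_id[k]), int(s.res_id[k]), str(s.res_name[k]))
        if key not in seen and key[2] in _rot.ROTAMERS:
            seen.add(key)
            out.append(key)
    return out


def _residue_mask(s: Structure, chain_id: str, res_id: int) -> np.ndarray:
    return (s.chain_id == chain_id) & (s.res_id == res_id) & (~s.is_het)


def _clash_energy(s: Structure, res_mask: np.ndarray, probe_xyz: np.ndarray,
                  probe_rad: np.ndarray, cfg: FlexConfig):
    """(soft clash energy, max overlap) of one residue's heavy atoms
    against the probe and the rest of the receptor."""
    heavy = s.heavy_mask
    own = res_mask & heavy
    others = heavy & ~res_mask
    o_xyz = s.coords[others]
    _, _, o_rad = _pair_tables(s.element[others])
    _, _, a_rad = _pair_tables(s.element[own])
    a_xyz = s.coords[own]
    energy = 0.0
    max_overlap = 0.0
    targets = [(probe_xyz, probe_rad), (o_xyz, o_rad)]
    for t_xyz, t_rad in targets:
        if len(t_xyz) == 0:
            continue
        tree = cKDTree(t_xyz)
        lists = tree.query_ball_point(a_xyz, 5.0)
        for a, nb in enumerate(lists):
            if not nb:
                continue
            nb = np.asarray(nb, dtype=int)
            d = np.linalg.norm(t_xyz[nb] - a_xyz[a], axis=1)
            # exclude covalently-bonded receptor neighbours by distance
            close = d > 1.0
            overlap = (a_rad[a] + t_rad[nb]) - d
            overlap = overlap[close]
            if len(overlap):
                mo = float(overlap.max())
                max_overlap = max(max_overlap, mo)
                excess = np.maximum(0.0, overlap - cfg.clash_distance)
                energy += cfg.clash_k * float(np.sum(excess**2)) * 10.0
    return energy, max_overlap


_ROTAMER_RANK_PENALTY = 0.05


def _chi_rank(res_name: str, chis) -> int:
    """Preference rank of a conformation: index of the nearest rotamer in
    the set (within 40 degrees on every chi), else one past the end."""
    rotamers = _rot.enumerate_rotamers(res_name)
    for rank, ref in enumerate(rotamers):
        if all(
            abs((a - b + 180.0) % 360.0 - 180.0) <= 40.0
            for a, b in zip(chis, ref)
        ):
            return rank
    return len(rotamers)


def repack_side_chains(s: Structure, pose: Pose,
                       cfg: FlexConfig | None = None):
    """Greedy rotamer repacking of residues near the probe.

    Residues with any heavy atom within ``repack_radius`` of the probe are
    re-assigned the rotamer minimising clash + rank preference, searched in
    order of worst clash over two sweeps.  If the best rotamer of a residue
    still clashes hard and backbone relaxation is enabled, the +/-2-residue
    window is shifted along the net clash direction (capped at
    ``max_backbone_shift``).

    Returns ``(variant, moved_residues, resolved)``; ``resolved`` is False
    when a hard clash (> clash_distance overlap) survives.
    """
    cfg = cfg or FlexConfig()
    variant = copy.deepcopy(s)
    probe_xyz = pose.coords
    probe_rad = np.full(len(probe_xyz), VDW_RADII["C"])
    residues = _residues_near(variant, probe_xyz, cfg.repack_radius)
    if not residues:
        return variant, [], True

    def worst(key):
        mask = _residue_mask(variant, key[0], key[1])
        return -_clash_energy(variant, mask, probe_xyz, probe_rad, cfg)[1]

    residues.sort(key=lambda k: (worst(k), k))
    moved = []
    for _sweep in range(2):
        for key in residues:
            cid, rid, rname = key
            mask = _residue_mask(variant, cid, rid)
            before = _rot.residue_chis(variant, cid, rid)
            if before is None:
                continue
            best = (None, np.inf)
            for rank, chis in enumerate(_rot.enumerate_rotamers(rname)):
                _rot.apply_rotamer(variant, cid, rid, chis)
                e, _ = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
                e += _ROTAMER_RANK_PENALTY * rank
                if e < best[1] - 1e-9:
                    best = (chis, e)
            # the starting conformation competes, carrying its own
            # rotamer-preference penalty (nearest entry of the set)
            _rot.apply_rotamer(variant, cid, rid, before)
            e0, _ = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
            e0 += _ROTAMER_RANK_PENALTY * _chi_rank(rname, before)
            if best[0] is not None and best[1] < e0 - 1e-9:
                _rot.apply_rotamer(variant, cid, rid, best[0])
                moved.append(
                    {"chain": cid, "res_id": rid, "res_name": rname,
                     "chis_from": tuple(np.round(before, 1)),
                     "chis_to": tuple(np.round(best[0], 1))}
                )
    # resolve residual hard clashes with optional local backbone shifts
    resolved = True
    for key in residues:
        cid, rid, rname = key
        mask = _residue_mask(variant, cid, rid)
        _, mo = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
        if mo <= cfg.clash_distance:
            continue
        if cfg.backbone_relax and _backbone_shift(
            variant, cid, rid, probe_xyz, probe_rad, cfg
        ):
            _, mo = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
        if mo > cfg.clash_distance:
            resolved = False
    # deduplicate moved records (last assignment wins)
    dedup = {}
    for m in moved:
        dedup[(m["chain"], m["res_id"])] = m
    return variant, sorted(dedup.values(), key=lambda m: (m["chain"], m["res_id"])), resolved


def _backbone_shift(variant, cid, rid, probe_xyz, probe_rad, cfg) -> bool:
    """Rigidly shift the +/-2-residue window away from the probe clash
    (steepest-descent on the soft clash penalty, <= 50 steps, capped)."""
    window = (
        (variant.chain_id == cid)
        & (np.abs(variant.res_id - rid) <= 2)
        & (~variant.is_het)
    )
    if not window.any():
        return False
    mask = _residue_mask(variant, cid, rid)
    start = variant.coords[window].copy()
    shift = np.zeros(3)
    step = 0.05
    for _ in range(50):
        e, mo = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
        if mo <= cfg.clash_distance:
            return True
        # net direction away from the probe atoms in overlap
        res_xyz = variant.coords[mask & variant.heavy_mask]
        tree = cKDTree(probe_xyz)
        d, j = tree.query(res_xyz, k=1)
        overlap = (probe_rad[j] + 1.7) - d
        push = res_xyz - probe_xyz[j]
        norms = np.linalg.norm(push, axis=1)
        ok = (overlap > 0) & (norms > 1e-9)
        if not ok.any():
            return True
        grad = (push[ok] / norms[ok, None] * overlap[ok, None]).sum(axis=0)
        n = np.linalg.norm(grad)
        if n < 1e-9:
            break
        delta = grad / n * step
        if np.linalg.norm(shift + delta) > cfg.max_backbone_shift:
            break
        shift += delta
        variant.coords[window] += delta
    _, mo = _clash_energy(variant, mask, probe_xyz, probe_rad, cfg)
    if mo > cfg.clash_distance + 1e-9 and np.linalg.norm(shift) < 1e-9:
        variant.coords[window] = start
        return False
    return mo <= cfg.clash_distance


# ---------------------------------------------------------------------------
# the induced-fit cycle


def _rescore_site(variant: Structure, anchor: np.ndarray,
                  det_cfg: DetectionConfig, weights: ScoreWeights,
                  cfg: FlexConfig) -> Site | None:
    """Re-detect and score the pocket nearest the anchor in a box of edge
    ``outer_box`` around it (probe removed)."""
    half = cfg.outer_box / 2.0
    bounds = (anchor - half, anchor + half)
    grid = detect_fields(variant, det_cfg, bounds=bounds)
    sites = find_sites(grid, det_cfg)
    if not sites:
        return None
    best = min(
        sites, key=lambda s: float(np.linalg.norm(s.centroid - anchor))
    )
    compute_descriptors(best, grid, det_cfg, weights)
    return best


def backbone_rmsd(a: Structure, b: Structure) -> float:
    """Heavy-atom backbone RMSD between two conformers of one structure."""
    names = np.isin(a.atom_name, ("N", "CA", "C", "O"))
    mask = names & a.heavy_mask & ~a.is_het
    if not mask.any():
        mask = a.heavy_mask & ~a.is_het  # pseudo-atom walls: all heavy atoms
    d = np.linalg.norm(a.coords[mask] - b.coords[mask], axis=1)
    return float(np.sqrt(np.mean(d**2)))


def induced_fit_cycle(s: PreparedStructure, site: Site,
                      cfg: FlexConfig | None = None,
                      det_cfg: DetectionConfig | None = None,
                      weights: ScoreWeights | None = None) -> list:
    """Run the two-stage probe protocol on one site.

    Returns the ``n_models_scored`` top models (by pose energy) with their
    re-scored sites; empty when naphthalene finds no admissible pose.
    """
    cfg = cfg or FlexConfig()
    det_cfg = det_cfg or DetectionConfig()
    weights = weights or ScoreWeights()
    anchor = site.points.mean(axis=0)

    naphthalene = Probe.from_name("naphthalene")
    tsn = Probe.from_name("TSN")

    ctx = _ReceptorContext(s, cfg)
    naph_poses = dock_probe(s, site, naphthalene, cfg, context=ctx)
    if not naph_poses:
        return []

    candidates = []
    for branch, pose in enumerate(
        _diverse_poses(naph_poses, cfg.n_naph_poses_kept)
    ):
        variant, moved1, ok = repack_side_chains(s, pose, cfg)
        if not ok:
            continue
        vctx = _ReceptorContext(variant, cfg)
        # the pocket has been opened: re-detect its site points so the TSN
        # search covers the newly exposed regions (union with the original
        # points keeps mouth placements available)
        opened = _rescore_site(variant, anchor, det_cfg, weights, cfg)
        if opened is not None:
            tsn_site = Site(
                site_id=site.site_id,
                points=np.unique(
                    np.vstack([site.points, opened.points]), axis=0
                ),
                n=0,
            )
            tsn_site.n = len(tsn_site.points)
        else:
            tsn_site = site
        # substituent torsions of the raw conformer almost always clash, so
        # the rigid core search admits every pose and the energy ceiling is
        # applied after greedy torsion refinement
        core_poses = dock_probe(
            variant, tsn_site, tsn, cfg, context=vctx, admit_all=True,
            outward_offsets=True,
        )
        per_variant = max(
            1, cfg.min_models_generated // max(1, cfg.n_naph_poses_kept)
        )
        refined = [
            _refine_torsions(tsn, p, vctx, cfg)
            for p in core_poses[: cfg.max_torsion_poses]
        ]
        refined = [p for p in refined if p.energy < cfg.admission_ceiling]
        refined.sort(key=lambda p: p.energy)
        for rank_in_branch, tp in enumerate(refined[:per_variant]):
            model, moved2, ok2 = repack_side_chains(variant, tp, cfg)
            if not ok2:
                continue
            rmsd = backbone_rmsd(s, model)
            if rmsd > cfg.max_backbone_shift + 1e-6:
                continue
            candidates.append(
                (rank_in_branch, branch, FlexModel(
                    receptor=model,
                    pose=tp,
                    pose_energy=tp.energy,
                    moved_residues=moved1 + moved2,
                    backbone_rmsd=rmsd,
                ))
            )

    # round-robin across naphthalene branches so every induced-fit branch
    # contributes its best models to the scored set
    candidates.sort(key=lambda c: (c[0], c[2].pose_energy, c[1]))
    scored = []
    for _, _, model in candidates[: cfg.n_models_scored]:
        model.site = _rescore_site(model.receptor, anchor, det_cfg, weights, cfg)
        if model.site is not None:
            scored.append(model)
    return scored


def flexible_result(models: list):
    """Per-site flexible outcome: the maximum re-scored Dscore+ over the
    models, with the volume of that same model (ties favour the larger
    volume)."""
    if not models:
        raise ValueError("no flexible models")
    with_sites = [m for m in models if m.site is not None and m.site.descriptors]
    if not with_sites:
        raise ValueError("no re-scored models")
    best = max(
        with_sites,
        key=lambda m: (
            m.site.descriptors.reported_dscore_plus,
            m.site.volume,
        ),
    )
    return best.site.descriptors.reported_dscore_plus, best.site.volume
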