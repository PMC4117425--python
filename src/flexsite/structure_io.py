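"""Reading, preparing and writing protein structures.

The preparation step mirrors a standard druggability-pipeline protocol:
waters are deleted, small ligands (molecular weight <= 1000 Da) are removed
except for a fixed keep-list of tight-binding cofactors (hemes, zinc,
magnesium), hydrogens are added by geometric placement, and missing
side-chain atoms are rebuilt from ideal residue templates.  Removed ligands
are recorded so that later stages can test whether a detected pocket
overlaps a crystallographic ligand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import rotamers as _rot

__all__ = [
    "KeepList",
    "RemovedLigand",
    "Structure",
    "PreparedStructure",
    "FormatError",
    "CalphaOnlyError",
    "EmptyProteinError",
    "read_structure",
    "prepare",
    "write_structure",
    "ligand_molecular_weight",
]

#: Het codes retained regardless of molecular weight: heme variants, zinc
#: and magnesium.  These are particularly tight-binding cofactors that are
#: effectively part of the receptor.
DEFAULT_KEEP_CODES = frozenset(
    {
        "HEM", "MHM", "HEV", "VER", "SRM", "HEO", "HEB", "HEC",
        "HDM", "HDD", "DDH", "ZN", "MG",
    }
)

WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

#: Threshold below which a het entity counts as a removable ligand (Da).
LIGAND_MW_MAX = 1000.0

# Standard atomic masses (Da) for the elements that occur in practice.
ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}


class FormatError(ValueError):
    """The input file could not be parsed as PDB."""


class CalphaOnlyError(ValueError):
    """More than half of the protein residues carry only a CA atom."""


class EmptyProteinError(ValueError):
    """No protein atoms present after filtering."""


@dataclass(frozen=True)
class KeepList:
    """Het codes exempt from ligand removal."""

    het_codes: frozenset = DEFAULT_KEEP_CODES


@dataclass
class RemovedLigand:
    """Registry entry for a het entity deleted during preparation."""

    name: str
    chain_id: str
    res_id: int
    molecular_weight: float
    coords: np.ndarray
    elements: np.ndarray

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "chain_id": self.chain_id,
            "res_id": self.res_id,
            "molecular_weight": round(self.molecular_weight, 2),
            "n_heavy_atoms": int(np.sum(self.elements != "H")),
        }


@dataclass
class Structure:
    """Flat atom-table representation of a (raw or prepared) structure.

    Coordinates are in Angstroms; residue numbering and chain ids follow the
    source file (author chain ids).
    """

    element: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    atom_name: np.ndarray
    is_het: np.ndarray

    def __len__(self) -> int:
        return len(self.element)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(self.element, ("H", "D"))

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.is_het

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask]

    def chains(self) -> dict:
        """Ordered residue-id lists per chain (protein residues only)."""
        out: dict[str, list[int]] = {}
        mask = self.protein_mask
        for cid, rid in zip(self.chain_id[mask], self.res_id[mask]):
            lst = out.setdefault(str(cid), [])
            if not lst or lst[-1] != int(rid):
                lst.append(int(rid))
        return out

    def n_residues_per_chain(self) -> dict:
        return {c: len(r) for c, r in self.chains().items()}

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            element=self.element[mask],
            coords=self.coords[mask],
            occupancy=self.occupancy[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            chain_id=self.chain_id[mask],
            atom_name=self.atom_name[mask],
            is_het=self.is_het[mask],
        )

    def residue_keys(self) -> np.ndarray:
        """Stable (chain, res_id, res_name, is_het) key per atom."""
        return np.array(
            [
                f"{c}|{r}|{n}|{int(h)}"
                for c, r, n, h in zip(
                    self.chain_id, self.res_id, self.res_name, self.is_het
                )
            ]
        )


@dataclass
class PreparedStructure(Structure):
    """Structure after water/ligand removal and hydrogen addition."""

    retained_cofactors: list = field(default_factory=list)
    removed_ligands: list = field(default_factory=list)

    def removal_log(self) -> dict:
        return {
            "retained_cofactors": list(self.retained_cofactors),
            "removed_ligands": [lig.to_json() for lig in self.removed_ligands],
        }

    def write_removal_log(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.removal_log(), fh, indent=2)


# ---------------------------------------------------------------------------
# reading


def _structure_from_gemmi(st: gemmi.Structure) -> Structure:
    if len(st) == 0:
        raise FormatError("file contains no models")
    model = st[0]  # first MODEL only
    rows = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                rows.append(
                    (
                        atom.element.name.upper(),
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                        atom.occ,
                        res.seqid.num,
                        res.name,
                        chain.name,
                        atom.name,
                        het,
                    )
                )
    if not rows:
        raise FormatError("no atom records found")
    el, xyz, occ, rid, rname, cid, aname, ishet = zip(*rows)
    return Structure(
        element=np.array(el, dtype="U2"),
        coords=np.array(xyz, dtype=float),
        occupancy=np.array(occ, dtype=float),
        res_id=np.array(rid, dtype=int),
        res_name=np.array(rname, dtype="U5"),
        chain_id=np.array(cid, dtype="U4"),
        atom_name=np.array(aname, dtype="U6"),
        is_het=np.array(ishet, dtype=bool),
    )


def _check_calpha_only(s: Structure) -> None:
    mask = s.protein_mask
    if not mask.any():
        return
    keys = {}
    for rid, cid, aname in zip(s.res_id[mask], s.chain_id[mask], s.atom_name[mask]):
        keys.setdefault((str(cid), int(rid)), set()).add(str(aname))
    n_ca_only = sum(1 for names in keys.values() if names == {"CA"})
    if keys and n_ca_only / len(keys) > 0.5:
        raise CalphaOnlyError(
            f"{n_ca_only}/{len(keys)} residues contain only CA atoms"
        )


def _het_entities(s: Structure):
    """Group het atoms into entities keyed by (chain, res_id, res_name)."""
    idx = np.flatnonzero(s.is_het)
    groups: dict[tuple, list[int]] = {}
    for i in idx:
        key = (str(s.chain_id[i]), int(s.res_id[i]), str(s.res_name[i]))
        groups.setdefault(key, []).append(int(i))
    return groups


def read_structure(path, assembly_mode: str = "as-deposited") -> Structure:
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB-format file (ATOM/HETATM/TER/MODEL records; first MODEL used).
    assembly_mode:
        ``"as-deposited"`` keeps every chain; ``"monomer:X"`` (or just a
        chain id) keeps protein chain ``X`` plus the het entities whose
        nearest protein heavy atom belongs to it (ties broken by chain-id
        order).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    s = _structure_from_gemmi(st)
    _check_calpha_only(s)

    if assembly_mode in ("as-deposited", None, ""):
        return s

    chain = assembly_mode.split(":", 1)[1] if ":" in assembly_mode else assembly_mode
    prot_chains = sorted(set(s.chain_id[s.protein_mask]))
    if chain not in prot_chains:
        raise ValueError(f"chain {chain!r} not found (have {prot_chains})")

    keep = np.zeros(len(s), dtype=bool)
    keep |= s.protein_mask & (s.chain_id == chain)

    # assign het entities to their nearest protein chain
    pmask = s.protein_mask & s.heavy_mask
    pxyz = s.coords[pmask]
    pchain = s.chain_id[pmask]
    for key, idxs in sorted(_het_entities(s).items()):
        hxyz = s.coords[idxs]
        d = np.linalg.norm(pxyz[None, :, :] - hxyz[:, None, :], axis=-1)
        # nearest chain; tie broken by chain-id order via stable sort over
        # (distance, chain id)
        per_chain = {}
        for c in prot_chains:
            sel = pchain == c
            if sel.any():
                per_chain[c] = float(d[:, sel].min())
        owner = min(per_chain, key=lambda c: (round(per_chain[c], 6), c))
        if owner == chain:
            keep[idxs] = True
    return s.subset(keep)


# ---------------------------------------------------------------------------
# molecular weight


def ligand_molecular_weight(res_name: str, elements: np.ndarray) -> float:
    """Molecular weight of a het entity in Da.

    For components known to the chemical component dictionary the full
    formula weight (implicit hydrogens included) is used; otherwise the
    masses of the atoms actually present are summed.
    """
    try:
        import biotite.structure.info as info

        return float(info.mass(res_name))
    except Exception:
        return float(sum(ATOMIC_MASS.get(str(e), 12.011) for e in elements))


# ---------------------------------------------------------------------------
# hydrogen placement and side-chain completion


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid transform (R, t) minimising |R P + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def _template(res_name: str):
    try:
        import biotite.structure.info as info

        tpl = info.residue(res_name)
    except Exception:
        return None
    if tpl is None or tpl.bonds is None:
        return None
    return tpl


def _residue_groups(s: Structure):
    order = []
    groups: dict[tuple, list[int]] = {}
    for i in range(len(s)):
        key = (str(s.chain_id[i]), int(s.res_id[i]), str(s.res_name[i]), bool(s.is_het[i]))
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(i)
    return order, groups


_TERMINAL_NAMES = {"OXT", "HXT", "H2", "H3", "HN2"}


def _complete_residue(res_name, names, coords, add_hydrogens=True):
    """Return (new_names, new_elements, new_coords) completing one residue.

    Missing heavy side-chain atoms are copied from the ideal template after
    superposition on the backbone; hydrogens are placed by transferring the
    template hydrogen through a local frame fitted on its bonded heavy atom
    and that atom's covalent neighbourhood.
    """
    tpl = _template(res_name)
    if tpl is None:
        return [], [], []
    t_names = list(tpl.atom_name)
    t_elem = list(tpl.element)
    t_xyz = np.asarray(tpl.coord, dtype=float)
    bonds = {i: set() for i in range(len(t_names))}
    for a, b, _ in tpl.bonds.as_array():
        bonds[int(a)].add(int(b))
        bonds[int(b)].add(int(a))
    t_index = {n: i for i, n in enumerate(t_names)}
    have = {n: coords[i] for i, n in enumerate(names)}

    new_names, new_elems, new_xyz = [], [], []

    # --- missing heavy atoms (rebuild from backbone-superposed template)
    backbone = [n for n in ("N", "CA", "C", "O", "CB") if n in have and n in t_index]
    missing_heavy = [
        n
        for n, e in zip(t_names, t_elem)
        if e != "H" and n not in have and n not in _TERMINAL_NAMES
    ]
    if missing_heavy and len(backbone) >= 3:
        P = np.array([t_xyz[t_index[n]] for n in backbone])
        Q = np.array([have[n] for n in backbone])
        R, t = _kabsch(P, Q)
        for n in missing_heavy:
            pos = R @ t_xyz[t_index[n]] + t
            new_names.append(n)
            new_elems.append(t_elem[t_index[n]])
            new_xyz.append(pos)
            have[n] = pos

    if not add_hydrogens:
        return new_names, new_elems, new_xyz

    # --- hydrogens via local-frame transfer
    for hi, (hn, he) in enumerate(zip(t_names, t_elem)):
        if he != "H" or hn in have or hn in _TERMINAL_NAMES:
            continue
        parents = [j for j in bonds[hi] if t_elem[j] != "H"]
        if not parents:
            continue
        p = parents[0]
        frame = {p}
        for j in bonds[p]:
            if t_elem[j] != "H":
                frame.add(j)
                for k in bonds[j]:
                    if t_elem[k] != "H":
                        frame.add(k)
        frame_names = [t_names[j] for j in sorted(frame) if t_names[j] in have]
        if len(frame_names) < 3:
            continue
        P = np.array([t_xyz[t_index[n]] for n in frame_names])
        Q = np.array([have[n] for n in frame_names])
        R, t = _kabsch(P, Q)
        new_names.append(hn)
        new_elems.append("H")
        new_xyz.append(R @ t_xyz[hi] + t)
    return new_names, new_elems, new_xyz


# ---------------------------------------------------------------------------
# preparation


def prepare(raw: Structure, keep_list: KeepList | None = None,
            add_hydrogens: bool = True) -> PreparedStructure:
    """Apply the preparation rules to a raw structure.

    Waters are removed; het entities with molecular weight <= 1000 Da are
    removed unless their code is on the keep-list; heavier het entities are
    retained and flagged as oversized; hydrogens are added geometrically and
    missing side-chain atoms are rebuilt to the residue's most common
    rotamer.
    """
    keep_list = keep_list or KeepList()
    if not raw.protein_mask.any():
        raise EmptyProteinError("structure has no protein atoms")

    keep = np.ones(len(raw), dtype=bool)
    retained: list[str] = []
    removed: list[RemovedLigand] = []
    for (cid, rid, rname), idxs in sorted(_het_entities(raw).items()):
        if rname in WATER_CODES:
            keep[idxs] = False
            continue
        mw = ligand_molecular_weight(rname, raw.element[idxs])
        if rname in keep_list.het_codes:
            retained.append(rname)
        elif mw <= LIGAND_MW_MAX:
            keep[idxs] = False
            removed.append(
                RemovedLigand(
                    name=rname,
                    chain_id=cid,
                    res_id=rid,
                    molecular_weight=mw,
                    coords=raw.coords[idxs].copy(),
                    elements=raw.element[idxs].copy(),
                )
            )
        else:
            retained.append(f"{rname}:oversized")

    s = raw.subset(keep)

    # complete protein residues: missing side chains + hydrogens
    order, groups = _residue_groups(s)
    add_names, add_elems, add_xyz, add_meta = [], [], [], []
    rebuilt_res = []
    for key in order:
        cid, rid, rname, het = key
        if het:
            continue
        idxs = groups[key]
        names = [str(s.atom_name[i]) for i in idxs]
        coords = s.coords[idxs]
        heavy_before = {n for i, n in zip(idxs, names) if s.element[i] != "H"}
        nn, ne, nx = _complete_residue(rname, names, coords, add_hydrogens)
        for n, e, x in zip(nn, ne, nx):
            add_names.append(n)
            add_elems.append(e)
            add_xyz.append(x)
            add_meta.append((cid, rid, rname))
            if e != "H" and n not in heavy_before:
                rebuilt_res.append((cid, rid, rname))

    if add_names:
        s = Structure(
            element=np.concatenate([s.element, np.array(add_elems, dtype="U2")]),
            coords=np.vstack([s.coords, np.array(add_xyz, dtype=float)]),
            occupancy=np.concatenate([s.occupancy, np.ones(len(add_names))]),
            res_id=np.concatenate(
                [s.res_id, np.array([m[1] for m in add_meta], dtype=int)]
            ),
            res_name=np.concatenate(
                [s.res_name, np.array([m[2] for m in add_meta], dtype="U5")]
            ),
            chain_id=np.concatenate(
                [s.chain_id, np.array([m[0] for m in add_meta], dtype="U4")]
            ),
            atom_name=np.concatenate(
                [s.atom_name, np.array(add_names, dtype="U6")]
            ),
            is_het=np.concatenate([s.is_het, np.zeros(len(add_names), dtype=bool)]),
        )

    out = PreparedStructure(
        element=s.element,
        coords=s.coords,
        occupancy=s.occupancy,
        res_id=s.res_id,
        res_name=s.res_name,
        chain_id=s.chain_id,
        atom_name=s.atom_name,
        is_het=s.is_het,
        retained_cofactors=sorted(set(retained)),
        removed_ligands=removed,
    )

    # rebuilt side chains adopt the residue's most common rotamer
    for cid, rid, rname in sorted(set(rebuilt_res)):
        chis = _rot.most_common_rotamer(rname)
        if chis is not None:
            _rot.apply_rotamer(out, cid, rid, chis)
    return out


# ---------------------------------------------------------------------------
# writing


def write_structure(s: Structure, path) -> None:
    """Write the structure as a PDB file (ATOM/HETATM records)."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    serial = 0
    for i in range(len(s)):
        cid = str(s.chain_id[i])
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
            model.add_chain(chain_map[cid])
            chain_map[cid] = model[len(model) - 1]
        key = (cid, int(s.res_id[i]), str(s.res_name[i]), bool(s.is_het[i]))
        if key not in res_map:
            res = gemmi.Residue()
            res.name = str(s.res_name[i])
            res.seqid = gemmi.SeqId(int(s.res_id[i]), " ")
            res.het_flag = "H" if s.is_het[i] else "A"
            chain_map[cid].add_residue(res)
            res_map[key] = chain_map[cid][len(chain_map[cid]) - 1]
        atom = gemmi.Atom()
        atom.name = str(s.atom_name[i])
        atom.element = gemmi.Element(str(s.element[i]).capitalize())
        atom.pos = gemmi.Position(*s.coords[i])
        atom.occ = float(s.occupancy[i])
        serial += 1
        atom.serial = serial
        res_map[key].add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_site_points_pdb(points: np.ndarray, path, res_name: str = "SIT") -> None:
    """Write site points as HETATM pseudo-atoms for visualisation."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(np.asarray(points, dtype=float), start=1):
            serial = i % 100000
            fh.write(
                f"HETATM{serial:5d}  C   {res_name} X{(i % 10000):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
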