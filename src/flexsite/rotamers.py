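"""Compact backbone-independent rotamer set and chi-rotation machinery.

The table lists, per residue type, the highest-frequency side-chain
rotamers (chi angles in degrees, most common first).  Values follow the
canonical gauche+/trans/gauche- wells of the penultimate-style rotamer
libraries; exact library frequencies are not required because repacking
re-scores every candidate rotamer against its environment.  Enumeration
optionally expands each base rotamer with +/-30 degree chi1 variants to
give the greedy repacker room around the wells.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CHI_ATOMS",
    "ROTAMERS",
    "most_common_rotamer",
    "enumerate_rotamers",
    "residue_chis",
    "apply_rotamer",
]

# chi dihedral atom quadruples per residue type
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# most common rotamers first; angles in degrees
ROTAMERS = {
    "ARG": [(-67, 180, 180, 180), (-67, 180, 65, 85), (180, 180, 180, 180),
            (-62, 180, 180, -85), (180, 65, 65, 85)],
    "ASN": [(-65, -20), (-177, 30), (62, -10), (-65, 120)],
    "ASP": [(-70, -15), (-177, 0), (62, -10)],
    "CYS": [(-65,), (-177,), (63,)],
    "GLN": [(-67, 180, -25), (-67, 180, 60), (180, 65, 60), (180, 180, 0)],
    "GLU": [(-67, 180, -10), (-67, -65, -40), (180, 65, 10), (180, 180, 0)],
    "HIS": [(-65, -70), (-177, 65), (62, -75), (-65, 165)],
    "ILE": [(-65, 170), (-57, -60), (62, 170), (-177, 165)],
    "LEU": [(-65, 175), (-177, 65), (-172, 145), (65, 175)],
    "LYS": [(-67, 180, 180, 180), (-67, 180, 180, 65), (180, 180, 180, 180),
            (-62, -68, 180, 180)],
    "MET": [(-65, -65, -70), (-67, 180, 75), (-67, 180, 180), (180, 65, 75)],
    "PHE": [(-65, 90), (-177, 80), (62, 90)],
    "SER": [(-65,), (62,), (-177,)],
    "THR": [(-65,), (62,), (-177,)],
    "TRP": [(-65, 95), (-177, -105), (-65, -5), (62, 90), (-177, 90)],
    "TYR": [(-65, 90), (-177, 80), (62, 90)],
    "VAL": [(175,), (-60,), (63,)],
}


def most_common_rotamer(res_name: str):
    rots = ROTAMERS.get(res_name)
    return rots[0] if rots else None


def enumerate_rotamers(res_name: str, expand_chi1: bool = True):
    """Base rotamers, optionally followed by +/-30 degree chi1 variants.

    Order encodes the preference ranking used by the repacker (earlier =
    more favourable).
    """
    rots = ROTAMERS.get(res_name)
    if not rots:
        return []
    out = [tuple(float(c) for c in r) for r in rots]
    if expand_chi1:
        for r in rots:
            for d in (-30.0, 30.0):
                out.append((float(r[0]) + d,) + tuple(float(c) for c in r[1:]))
    return out


# ---------------------------------------------------------------------------
# geometry


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def _template_graph(res_name: str):
    try:
        import biotite.structure.info as info

        tpl = info.residue(res_name)
    except Exception:
        return None
    if tpl is None or tpl.bonds is None:
        return None
    names = list(tpl.atom_name)
    adj = {n: set() for n in names}
    for a, b, _ in tpl.bonds.as_array():
        adj[names[int(a)]].add(names[int(b)])
        adj[names[int(b)]].add(names[int(a)])
    return adj


def _moving_atoms(res_name: str, axis: tuple) -> set:
    """Atom names distal to the axis bond B-C (on the C side)."""
    adj = _template_graph(res_name)
    if adj is None:
        return set()
    b, c = axis
    seen = {b, c}
    stack = [c]
    moving = set()
    while stack:
        cur = stack.pop()
        for nb in adj.get(cur, ()):
            if nb not in seen:
                seen.add(nb)
                moving.add(nb)
                stack.append(nb)
    return moving


def residue_chis(s, chain_id: str, res_id: int):
    """Current chi angles of a residue, or None when undefined."""
    rname, idx = _residue_atoms(s, chain_id, res_id)
    if rname not in CHI_ATOMS:
        return None
    pos = {str(s.atom_name[i]): s.coords[i] for i in idx}
    chis = []
    for quad in CHI_ATOMS[rname]:
        if not all(a in pos for a in quad):
            return None
        chis.append(dihedral(*(pos[a] for a in quad)))
    return tuple(chis)


def _residue_atoms(s, chain_id: str, res_id: int):
    mask = (s.chain_id == chain_id) & (s.res_id == res_id) & (~s.is_het)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise KeyError(f"residue {chain_id}/{res_id} not found")
    return str(s.res_name[idx[0]]), idx


def apply_rotamer(s, chain_id: str, res_id: int, chis) -> bool:
    """Rotate a residue's side chain (in place) to the given chi angles.

    Returns True when all requested chis could be applied.  Backbone atoms
    (and CB position) are untouched; hydrogens follow their heavy atoms
    through the template connectivity.
    """
    rname, idx = _residue_atoms(s, chain_id, res_id)
    quads = CHI_ATOMS.get(rname)
    if not quads:
        return False
    name_to_idx = {str(s.atom_name[i]): int(i) for i in idx}
    ok = True
    for quad, target in zip(quads, chis):
        if not all(a in name_to_idx for a in quad):
            ok = False
            continue
        p = [s.coords[name_to_idx[a]] for a in quad]
        current = dihedral(*p)
        delta = float(target) - current
        if abs(delta) < 1e-9:
            continue
        axis_b, axis_c = quad[1], quad[2]
        moving = _moving_atoms(rname, (axis_b, axis_c))
        move_idx = [name_to_idx[n] for n in moving if n in name_to_idx]
        if not move_idx:
            ok = False
            continue
        origin = s.coords[name_to_idx[axis_b]]
        axis = s.coords[name_to_idx[axis_c]] - origin
        R = _rotation_about_axis(axis, delta)
        s.coords[move_idx] = (s.coords[move_idx] - origin) @ R.T + origin
    return ok
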