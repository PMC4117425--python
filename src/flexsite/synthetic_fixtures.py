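"""Synthetic receptor fixtures with analytic ground truth.

Protein-like atom clouds (dense pseudo-atom walls at ~1.8 A packing,
written as legal PDB ATOM records) realise cavities of controlled volume,
enclosure, lining polarity and -- for the gated kind -- a rotamer-gated
cryptic opening built from a real tryptophan residue so that the rotamer
machinery applies.  Ground truth is computed from the constructed geometry
by direct integration, independently of the detection pipeline.

Kinds
-----
``spherical_cavity``     closed hollow shell, void radius ``radius``
``hemispherical_pocket`` half-ball pocket of radius ``radius`` sunk into a
                         slab surface (mouth plane z = 0, centre at origin)
``slab``                 featureless flat block -- no pocket anywhere
``two_cavity``           two hemispherical pockets ``separation`` apart
``gated_cavity``         surface pocket whose adjacent buried lobe is
                         filled by a tryptophan side chain; the preferred
                         rotamer vacates it into solvent
``deep_pocket``          rigid drug-like surface pocket on the same
                         globular wall ball (no repackable residues)
``reference_pocket``     300 A^3 hemispherical pocket used as the
                         normalisation anchor of the phobic/philic fields
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rotamers as _rot
from .structure_io import PreparedStructure, write_structure

__all__ = ["FixtureSpec", "FixtureTruth", "generate", "write_fixture"]

ATOM_SPACING = 1.8     # lattice / shell packing distance, A
WALL_RADIUS = 1.7      # vdW radius of the pseudo-atom carbon wall
REFERENCE_POCKET_VOLUME = 300.0  # A^3


class FixtureSpecError(ValueError):
    """Geometrically infeasible fixture parameters."""


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    radius: float = 5.0            # cavity/pocket radius, A
    slab_size: float = 22.0        # lateral extent of slab-based fixtures, A
    wall_thickness: float = 5.0    # solid wall behind the void, A
    apolar_fraction: float = 1.0   # fraction of apolar (C) wall atoms
    separation: float = 16.0       # pocket-centre distance (two_cavity), A
    gate_residue: str = "TRP"
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.slab_size <= 0 or self.separation <= 0:
            raise FixtureSpecError("geometry parameters must be positive")
        if self.wall_thickness < ATOM_SPACING:
            raise FixtureSpecError(
                f"wall thinner than the atom packing distance ({ATOM_SPACING} A)"
            )
        if not 0.0 <= self.apolar_fraction <= 1.0:
            raise FixtureSpecError("apolar_fraction must lie in [0, 1]")


@dataclass
class FixtureTruth:
    """Analytic expectations for a generated fixture."""

    cavity_volume: float | None = None   # A^3 (closed state for gated)
    open_volume: float | None = None     # A^3 after the gate opens
    mouth_center: np.ndarray | None = None
    site_exists: bool = True
    n_cavities: int = 0
    gate: dict | None = None             # chain, res_id, open/closed chis


# ---------------------------------------------------------------------------
# geometric primitives


def _sphere_points(radius: float, spacing: float = ATOM_SPACING) -> np.ndarray:
    """Quasi-uniform points on a sphere at roughly hexagonal packing."""
    n = max(12, int(np.ceil(4.0 * np.pi * radius**2 / (0.866 * spacing**2))))
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return radius * np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _lattice(lo: np.ndarray, hi: np.ndarray, spacing: float = ATOM_SPACING) -> np.ndarray:
    """Cubic lattice anchored at ``hi`` (top planes sit exactly at hi)."""
    axes = []
    for k in range(3):
        n = int(np.floor((hi[k] - lo[k]) / spacing)) + 1
        axes.append(hi[k] - spacing * np.arange(n)[::-1])
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def _box_distance(points: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    d = np.maximum(np.maximum(lo - points, points - hi), 0.0)
    return np.linalg.norm(d, axis=1)


def _assign_elements(n: int, apolar_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    apolar = rng.random(n) < apolar_fraction
    return np.where(apolar, "C", "O").astype("U2")


def _pseudo_structure(coords: np.ndarray, elements: np.ndarray,
                      chain: str = "A") -> PreparedStructure:
    n = len(coords)
    return PreparedStructure(
        element=np.asarray(elements, dtype="U2"),
        coords=np.asarray(coords, dtype=float),
        occupancy=np.ones(n),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ZQX", dtype="U5"),
        chain_id=np.full(n, chain, dtype="U4"),
        atom_name=np.asarray(elements, dtype="U6"),
        is_het=np.zeros(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# simple kinds


def _spherical_cavity(spec: FixtureSpec):
    r = spec.radius
    shells = []
    t = 0.0
    while t < spec.wall_thickness - 1e-9:
        shells.append(_sphere_points(r + WALL_RADIUS + t))
        t += 1.5
    coords = np.vstack(shells)
    elements = _assign_elements(len(coords), spec.apolar_fraction, spec.seed)
    # each inner-shell atom sits at r + its own vdW radius so the void
    # boundary is the designed sphere regardless of lining composition
    from .site_grid import atom_vdw_radii

    n_inner = len(shells[0])
    radial = np.linalg.norm(coords[:n_inner], axis=1, keepdims=True)
    target = r + atom_vdw_radii(elements[:n_inner])[:, None]
    coords[:n_inner] *= target / radial
    truth = FixtureTruth(
        cavity_volume=4.0 / 3.0 * np.pi * r**3,
        site_exists=r >= 2.6,
        n_cavities=1,
    )
    return _pseudo_structure(coords, elements), truth


def _slab_block(L: float, depth: float, carve=None) -> np.ndarray:
    """Lattice atoms of a slab whose top envelope is the z = 0 plane."""
    lo = np.array([-L / 2 + WALL_RADIUS, -L / 2 + WALL_RADIUS, -depth + WALL_RADIUS])
    hi = np.array([L / 2 - WALL_RADIUS, L / 2 - WALL_RADIUS, -WALL_RADIUS])
    pts = _lattice(lo, hi)
    if carve is not None:
        pts = pts[~carve(pts)]
    return pts


def _hemisphere(spec: FixtureSpec, centers=((0.0, 0.0),)):
    r = spec.radius
    depth = r + spec.wall_thickness
    centers3 = [np.array([cx, cy, 0.0]) for cx, cy in centers]

    def carve(p):
        hit = np.zeros(len(p), dtype=bool)
        for c in centers3:
            hit |= np.linalg.norm(p - c, axis=1) <= r + WALL_RADIUS
        return hit

    coords = _slab_block(spec.slab_size, depth, carve)
    elements = _assign_elements(len(coords), spec.apolar_fraction, spec.seed)
    truth = FixtureTruth(
        cavity_volume=2.0 / 3.0 * np.pi * r**3,
        mouth_center=np.array(centers3[0]),
        site_exists=r >= 3.6,
        n_cavities=len(centers3),
    )
    return _pseudo_structure(coords, elements), truth


def _slab(spec: FixtureSpec):
    coords = _slab_block(spec.slab_size, max(6.0, spec.wall_thickness))
    elements = _assign_elements(len(coords), spec.apolar_fraction, spec.seed)
    return _pseudo_structure(coords, elements), FixtureTruth(
        cavity_volume=None, site_exists=False, n_cavities=0
    )


def _two_cavity(spec: FixtureSpec):
    if spec.separation < 2 * spec.radius + 4.0:
        raise FixtureSpecError("pockets overlap or nearly touch")
    half = spec.separation / 2.0
    if spec.slab_size < spec.separation + 2 * spec.radius + 6.0:
        spec = FixtureSpec(
            **{**spec.__dict__, "slab_size": spec.separation + 2 * spec.radius + 8.0}
        )
    s, truth = _hemisphere(spec, centers=((-half, 0.0), (half, 0.0)))
    truth.n_cavities = 2
    return s, truth


def _reference_pocket(spec: FixtureSpec):
    r = (3.0 * REFERENCE_POCKET_VOLUME / (2.0 * np.pi)) ** (1.0 / 3.0)
    spec2 = FixtureSpec(
        kind="hemispherical_pocket", radius=r, slab_size=spec.slab_size,
        wall_thickness=spec.wall_thickness,
        apolar_fraction=spec.apolar_fraction, seed=spec.seed,
    )
    s, truth = _hemisphere(spec2)
    truth.cavity_volume = REFERENCE_POCKET_VOLUME
    return s, truth


# ---------------------------------------------------------------------------
# gated cavity


def _trp_template_atoms():
    import biotite.structure.info as info

    tpl = info.residue("TRP")
    keep = [
        i for i, n in enumerate(tpl.atom_name)
        if n not in ("OXT", "HXT", "H2", "H3")
    ]
    names = [str(tpl.atom_name[i]) for i in keep]
    elems = [str(tpl.element[i]) for i in keep]
    xyz = np.asarray(tpl.coord, dtype=float)[keep]
    return names, elems, xyz


def _orient_residue(names, xyz, ca_pos, cb_dir, n_dir_hint):
    """Place a residue: CA at ``ca_pos``, CA->CB along ``cb_dir``; the
    residual roll fixed by pointing N as close to ``n_dir_hint`` as the
    geometry allows."""
    idx = {n: i for i, n in enumerate(names)}
    ca, cb, n_at = xyz[idx["CA"]], xyz[idx["CB"]], xyz[idx["N"]]
    local = xyz - ca
    u = (cb - ca) / np.linalg.norm(cb - ca)
    t = np.asarray(cb_dir, dtype=float)
    t /= np.linalg.norm(t)
    # rotation taking u -> t
    v = np.cross(u, t)
    c = float(np.dot(u, t))
    if np.linalg.norm(v) < 1e-12:
        R1 = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    local = local @ R1.T
    # roll about t to align N projection with hint
    nvec = local[idx["N"]]
    nproj = nvec - np.dot(nvec, t) * t
    h = np.asarray(n_dir_hint, dtype=float)
    hproj = h - np.dot(h, t) * t
    if np.linalg.norm(nproj) > 1e-9 and np.linalg.norm(hproj) > 1e-9:
        a = nproj / np.linalg.norm(nproj)
        b = hproj / np.linalg.norm(hproj)
        ang = np.arctan2(np.dot(np.cross(a, b), t), np.dot(a, b))
        R2 = _rot._rotation_about_axis(t, np.degrees(ang))
        local = local @ R2.T
    return local + np.asarray(ca_pos, dtype=float)


# Gated-cavity geometry.  A globular lattice ball keeps the outer surface
# convex (no shallow halo sites).  A fluorine-lined surface pocket sits at
# the top of the ball; the tryptophan gate is anchored at the pocket rim
# with its side chain, in the *built* (closed, second-preference) rotamer,
# filling a buried lobe just below the pocket.  The preferred rotamer
# points into solvent at the surface, so repacking around any docked probe
# swings the side chain out and merges the vacated lobe with the pocket.
_GATE_BALL_R = 8.6                          # lattice ball radius
_GATE_POCKET_C = np.array([-0.8, 0.8, 7.2])  # surface-pocket sphere centre
_GATE_POCKET_R = 2.45                       # pocket void radius, A
_GATE_CA = np.array([6.4, 0.0, 6.6])
_GATE_CB_DIR = np.array([-0.6, 0.0, -1.0])
_GATE_ROLL_HINT = np.array([0.0, 0.0, 1.0])
_GATE_CLOSED = (62.0, 90.0)      # low-preference rotamer, buried lobe
_GATE_OPEN = (-177.0, -105.0)    # preferred clash-free rotamer, outer flank
_GATE_SC_CLEARANCE = 0.3         # void shell around the closed side chain, A
#: carved voids are lined with fluorine pseudo-atoms: the smaller radius and
#: shorter-range probe minimum keep sub-100 A^3 cavities energetically
#: favourable; fluorine counts as hydrophobic (like a fluorocarbon lining)
#: and enters neither polar field
_LINING_RADIUS = 1.5
_LINING_DEPTH = 1.9


def _gate_trp(spec: FixtureSpec, res_id: int):
    """Build the gate residue (closed conformation) plus the side-chain
    coordinates of both the closed and the open rotamer."""
    names, elems, xyz = _trp_template_atoms()
    placed = _orient_residue(names, xyz, _GATE_CA, _GATE_CB_DIR, _GATE_ROLL_HINT)
    res = PreparedStructure(
        element=np.array(elems, dtype="U2"),
        coords=placed.copy(),
        occupancy=np.ones(len(names)),
        res_id=np.full(len(names), res_id),
        res_name=np.full(len(names), spec.gate_residue, dtype="U5"),
        chain_id=np.full(len(names), "A", dtype="U4"),
        atom_name=np.array(names, dtype="U6"),
        is_het=np.zeros(len(names), dtype=bool),
    )
    _rot.apply_rotamer(res, "A", res_id, _GATE_OPEN)
    open_ = res.coords.copy()
    _rot.apply_rotamer(res, "A", res_id, _GATE_CLOSED)
    closed = res.coords.copy()
    return res, closed, open_


_BACKBONE_NAMES = {"N", "CA", "C", "O", "CB", "H", "HA", "HB2", "HB3"}


def _gate_ball_lattice():
    """Solid cubic-lattice ball (convex outer surface)."""
    n = int(np.floor(_GATE_BALL_R / ATOM_SPACING))
    ax = ATOM_SPACING * np.arange(-n, n + 1)
    g = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    return pts[np.linalg.norm(pts, axis=1) <= _GATE_BALL_R + 1e-9]


def _gated_cavity(spec: FixtureSpec):
    lattice = _gate_ball_lattice()
    res, closed_xyz, open_xyz = _gate_trp(spec, res_id=1)

    heavy = res.element != "H"
    sc = np.array([n not in _BACKBONE_NAMES for n in res.atom_name])
    sc_heavy = np.flatnonzero(heavy & sc)
    bb_heavy = np.flatnonzero(heavy & ~sc)
    hydro = np.flatnonzero(~heavy)
    moat = WALL_RADIUS + _LINING_RADIUS + _GATE_SC_CLEARANCE

    def carve_pocket(p, pad=0.0):
        """Voids that become part of the binding site (fluorine-lined)."""
        hit = (
            np.linalg.norm(p - _GATE_POCKET_C, axis=1)
            <= _GATE_POCKET_R + _LINING_RADIUS + pad
        )
        for a in sc_heavy:                  # buried lobe around the closed side chain
            hit |= np.linalg.norm(p - closed_xyz[a], axis=1) <= moat + pad
        return hit

    def carve_clearance(p):
        """Snug crevices that merely make room for the residue and its
        open rotamer (plain carbon walls: too narrow to host site
        points)."""
        hit = np.zeros(len(p), dtype=bool)
        for a in sc_heavy:
            hit |= np.linalg.norm(p - open_xyz[a], axis=1) <= 2.9
        for a in bb_heavy:
            hit |= np.linalg.norm(p - res.coords[a], axis=1) <= 2.9
        for a in hydro:
            hit |= np.linalg.norm(p - res.coords[a], axis=1) <= 2.4
            hit |= np.linalg.norm(p - open_xyz[a], axis=1) <= 2.4
        return hit

    keep = ~(carve_pocket(lattice) | carve_clearance(lattice))
    lining = carve_pocket(lattice, _LINING_DEPTH) & keep
    lattice = lattice[keep]
    elements = _assign_elements(len(lattice), spec.apolar_fraction, spec.seed)
    elements[lining[keep]] = "F"
    wall = _pseudo_structure(lattice, elements)
    gate_id = len(lattice) + 1
    res.res_id[:] = gate_id

    s = PreparedStructure(
        element=np.concatenate([wall.element, res.element]),
        coords=np.vstack([wall.coords, res.coords]),
        occupancy=np.concatenate([wall.occupancy, res.occupancy]),
        res_id=np.concatenate([wall.res_id, res.res_id]),
        res_name=np.concatenate([wall.res_name, res.res_name]),
        chain_id=np.concatenate([wall.chain_id, res.chain_id]),
        atom_name=np.concatenate([wall.atom_name, res.atom_name]),
        is_het=np.concatenate([wall.is_het, res.is_het]),
    )

    region_centers = closed_xyz[sc_heavy]
    closed_v = _gated_void_volume(s, region_centers, include_lobe=False)
    s_open = _with_gate_rotamer(s, gate_id, _GATE_OPEN)
    open_v = _gated_void_volume(s_open, region_centers, include_lobe=True)

    truth = FixtureTruth(
        cavity_volume=closed_v,
        open_volume=open_v,
        mouth_center=np.array([0.0, 0.0, _GATE_BALL_R + WALL_RADIUS]),
        site_exists=True,
        n_cavities=1,
        gate={
            "chain": "A",
            "res_id": int(gate_id),
            "res_name": spec.gate_residue,
            "closed_chis": _GATE_CLOSED,
            "open_chis": _GATE_OPEN,
        },
    )
    return s, truth


def _with_gate_rotamer(s: PreparedStructure, gate_id: int, chis):
    import copy

    s2 = copy.deepcopy(s)
    _rot.apply_rotamer(s2, "A", gate_id, chis)
    return s2


def _gated_void_volume(s: PreparedStructure, region_centers: np.ndarray,
                       include_lobe: bool = True,
                       spacing: float = 0.35) -> float:
    """Void volume of the designed cavity region by direct integration.

    The region is the designed surface pocket (plus, for the open state,
    the lobe vacated by the gate side chain); cells outside the all-atom
    vdW envelope are counted.  Independent of the detection pipeline.
    """
    from scipy.spatial import cKDTree

    from .site_grid import atom_vdw_radii

    lo = np.array([-4.5, -6.5, 0.5])
    hi = np.array([7.5, 4.5, 10.2])
    axes = [np.arange(lo[k], hi[k] + 1e-9, spacing) for k in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)

    region = np.linalg.norm(pts - _GATE_POCKET_C, axis=1) <= _GATE_POCKET_R + 0.45
    if include_lobe:
        tree_r = cKDTree(region_centers)
        d, _ = tree_r.query(pts, k=1)
        region |= d <= 2.0
    region &= np.linalg.norm(pts, axis=1) <= _GATE_BALL_R + 1.0
    pts = pts[region]

    mask = s.heavy_mask
    xyz = s.coords[mask]
    radii = atom_vdw_radii(s.element[mask])
    tree = cKDTree(xyz)
    nb = tree.query_ball_point(pts, float(radii.max()) + 1e-6)
    void = np.ones(len(pts), dtype=bool)
    for i, lst in enumerate(nb):
        if lst and np.any(np.linalg.norm(xyz[lst] - pts[i], axis=1) <= radii[lst]):
            void[i] = False
    return float(void.sum() * spacing**3)


def _deep_pocket(spec: FixtureSpec):
    """Drug-like rigid pocket: a fluorine-lined spherical void of radius
    ``radius`` (default 3.4 A) opening at the surface of the globular wall
    ball.  No repackable residues exist, so flexibility modeling cannot
    enlarge it."""
    r = spec.radius if spec.radius != 5.0 else 3.4
    # wall_thickness beyond the 5 A default sinks the pocket deeper,
    # shrinking the mouth (used for burial/enclosure families)
    sink = 0.6 + max(0.0, spec.wall_thickness - 5.0)
    center = np.array([0.0, 0.0, _GATE_BALL_R - r - sink])
    lattice = _gate_ball_lattice()

    def carve(p, pad=0.0):
        return np.linalg.norm(p - center, axis=1) <= r + _LINING_RADIUS + pad

    keep = ~carve(lattice)
    lining = carve(lattice, _LINING_DEPTH) & keep
    lattice = lattice[keep]
    elements = _assign_elements(len(lattice), spec.apolar_fraction, spec.seed)
    elements[lining[keep]] = "F"
    s = _pseudo_structure(lattice, elements)
    truth = FixtureTruth(
        cavity_volume=4.0 / 3.0 * np.pi * r**3,
        mouth_center=np.array([0.0, 0.0, _GATE_BALL_R + WALL_RADIUS]),
        site_exists=True,
        n_cavities=1,
    )
    return s, truth


# ---------------------------------------------------------------------------
# public API

_BUILDERS = {
    "spherical_cavity": _spherical_cavity,
    "hemispherical_pocket": _hemisphere,
    "slab": _slab,
    "two_cavity": _two_cavity,
    "gated_cavity": _gated_cavity,
    "deep_pocket": _deep_pocket,
    "reference_pocket": _reference_pocket,
}


def generate(spec: FixtureSpec):
    """Deterministically build a fixture: (PreparedStructure, FixtureTruth)."""
    if spec.kind not in _BUILDERS:
        raise FixtureSpecError(
            f"unknown kind {spec.kind!r}; choose from {sorted(_BUILDERS)}"
        )
    return _BUILDERS[spec.kind](spec)


def write_fixture(spec: FixtureSpec, pdb_path, truth_path=None):
    """Write the fixture as a PDB file (plus optional truth JSON)."""
    import json

    s, truth = generate(spec)
    write_structure(s, pdb_path)
    if truth_path is not None:
        payload = {
            "kind": spec.kind,
            "cavity_volume": truth.cavity_volume,
            "open_volume": truth.open_volume,
            "mouth_center": None if truth.mouth_center is None
            else [float(x) for x in truth.mouth_center],
            "site_exists": truth.site_exists,
            "n_cavities": truth.n_cavities,
            "gate": truth.gate,
        }
        with open(truth_path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return s, truth
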