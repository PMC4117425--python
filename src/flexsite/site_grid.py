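"""Receptor grid and per-point site-point fields.

A regular grid is laid over the receptor (8 A margin).  Grid points are
classified by three per-point quantities:

* ``vdw_energy`` -- 6-12 Lennard-Jones interaction of a neutral united-atom
  carbon probe with all receptor heavy atoms within a cutoff.  Points inside
  the receptor van der Waals envelope carry a +inf sentinel.
* ``enclosure_fraction`` -- fraction of a fixed quasi-uniform set of radial
  rays whose first intersection with the receptor envelope lies within
  ``maxdist`` of the point.  Buried points approach 1, open surface points
  fall below ~0.45.
* ``phobic_potential`` / ``philic_potential`` -- distance-weighted contact
  sums over apolar carbons and polar (N/O, charged doubled) atoms with a
  (1 - r/6)^2 kernel, normalised to a packaged reference-pocket scale.

A *site point* is a grid point outside the receptor that is reasonably
enclosed (>= ``enclosure_min``) and has favourable probe energy
(<= -``maxvdw`` kcal/mol).  The combination selects the attractive shell of
concave pockets while rejecting flat solvent-exposed surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "DetectionConfig",
    "SiteGrid",
    "MemoryBudgetError",
    "build_grid",
    "vdw_energy_field",
    "enclosure_field",
    "phobic_philic_fields",
    "mark_site_points",
    "detect_fields",
    "fibonacci_sphere",
    "probe_pair_params",
]

# van der Waals radii used for the receptor envelope (A)
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.90, "MN": 1.40,
    "NA": 2.27, "K": 2.75, "SE": 1.90, "CU": 1.40, "NI": 1.40, "CO": 1.40,
}
DEFAULT_VDW_RADIUS = 1.70

# Lennard-Jones parameters: Rmin/2 (A) and well depth (kcal/mol) per
# element, combined with the probe by Lorentz-Berthelot rules.  The probe is
# a neutral aliphatic-carbon-like united atom (Rmin/2 = 2.5, eps = 0.043),
# giving a 5.0 A pair minimum with carbon at 0.08 kcal/mol depth.  The
# enlarged, shallow probe makes the site-point test selective for concave
# regions: above a flat wall the summed attraction peaks near |E| ~ 0.9
# kcal/mol (below the maxvdw threshold), while points ringed by cavity
# walls accumulate several-fold stronger attraction.
# The pair parameters are deliberately uniform across the organic
# elements: the probe field measures pocket *shape*; chemical character
# enters through the separate phobic/philic potentials.  Fluorine keeps a
# shorter-range, shallower minimum (small atom), metals their own
# parameters.
LJ_PARAMS = {
    "C": (2.00, 0.150), "N": (2.00, 0.150), "O": (2.00, 0.150),
    "S": (2.00, 0.150), "P": (2.00, 0.150), "F": (1.65, 0.100),
    "CL": (2.00, 0.150), "BR": (2.10, 0.150), "I": (2.25, 0.150),
    "FE": (1.30, 0.200), "ZN": (1.10, 0.250), "MG": (0.95, 0.200),
    "CA": (1.40, 0.240), "SE": (2.10, 0.290), "NA": (1.40, 0.100),
    "K": (1.75, 0.100), "MN": (1.30, 0.200), "CU": (1.20, 0.250),
    "NI": (1.20, 0.250), "CO": (1.20, 0.250),
}
PROBE_RMIN2 = 2.50
PROBE_EPS = 0.043

#: Normalisation scales fixing the mean phobic/philic potential over the
#: site points of the packaged reference pocket (300 A^3 hemispherical
#: pocket; fully apolar lining for the phobic scale, fully polar lining for
#: the philic scale) to 1.0.  See docs/methods.md.
PHOBIC_REFERENCE_MEAN = 0.6057
PHILIC_REFERENCE_MEAN = 0.6108


class MemoryBudgetError(MemoryError):
    """Grid would exceed the configured point budget."""


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the site-point detection stage.

    The first eight fields follow the tuned pocket-finder settings used for
    shallow/flexible-pocket mining; the remainder are implementation
    constants of this package.
    """

    grid_spacing: float = 0.35       # A
    maxdist: float = 10.0            # A, enclosure ray range
    enclosure_min: float = 0.4       # min fraction of rays striking receptor
    maxvdw: float = 1.0              # kcal/mol magnitude of probe energy
    dthresh: float = 5.0             # A, site joining distance
    neighbor_radius: float = 1.76    # A, sqrt(d2thresh) support radius
    nthresh: int = 7                 # min neighbours for a supported point
    mingroup: int = 7                # min points per site
    modphobic: int = 0               # 0 = raw (unmodulated) phobic potential
    n_rays: int = 110
    max_sites: int = 5
    margin: float = 8.0              # A, grid margin around the receptor
    vdw_cutoff: float = 8.0          # A, probe energy cutoff
    polar_radius: float = 6.0        # A, phobic/philic kernel range
    volume_reach: float = 2.75        # A, site-point dilation for volume
    max_points: int = 80_000_000

    def __post_init__(self):
        if min(self.grid_spacing, self.maxdist, self.dthresh,
               self.neighbor_radius, self.margin) <= 0:
            raise ValueError("distances must be positive")
        if self.nthresh < 1 or self.mingroup < 1:
            raise ValueError("nthresh and mingroup must be >= 1")
        if not 0.0 <= self.enclosure_min <= 1.0:
            raise ValueError("enclosure_min must lie in [0, 1]")


@dataclass
class SiteGrid:
    """Regular grid with per-point fields (C-ordered ``dims`` arrays)."""

    origin: np.ndarray
    spacing: float
    dims: tuple
    inside_receptor: np.ndarray
    vdw_energy: np.ndarray | None = None
    enclosure_fraction: np.ndarray | None = None
    phobic_potential: np.ndarray | None = None
    philic_potential: np.ndarray | None = None
    is_site_point: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def axes(self):
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.dims[k])
            for k in range(3)
        )

    def point_coords(self, mask: np.ndarray) -> np.ndarray:
        """Cartesian coordinates of the points selected by a dims-mask."""
        idx = np.argwhere(mask)
        return self.origin[None, :] + idx * self.spacing

    def index_of(self, coords: np.ndarray) -> np.ndarray:
        """Nearest grid indices (n, 3) of cartesian points."""
        return np.rint((np.asarray(coords) - self.origin) / self.spacing).astype(int)

    def dump(self, prefix) -> None:
        """Binary field dump with a JSON sidecar (origin, spacing, dims)."""
        import json

        arrays = {
            "inside_receptor": self.inside_receptor,
            "vdw_energy": self.vdw_energy,
            "enclosure_fraction": self.enclosure_fraction,
            "phobic_potential": self.phobic_potential,
            "philic_potential": self.philic_potential,
            "is_site_point": self.is_site_point,
        }
        np.savez(f"{prefix}.npz", **{k: v for k, v in arrays.items() if v is not None})
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "origin": [float(x) for x in self.origin],
                    "spacing": self.spacing,
                    "dims": list(self.dims),
                },
                fh,
            )


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def probe_pair_params(elements: np.ndarray):
    """Per-atom (r_min, eps) of the probe-atom Lennard-Jones pair."""
    rmin = np.empty(len(elements))
    eps = np.empty(len(elements))
    for i, e in enumerate(elements):
        r2, ep = LJ_PARAMS.get(str(e), LJ_PARAMS["C"])
        rmin[i] = PROBE_RMIN2 + r2
        eps[i] = np.sqrt(PROBE_EPS * ep)
    return rmin, eps


def atom_vdw_radii(elements: np.ndarray) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e), DEFAULT_VDW_RADIUS) for e in elements])


# ---------------------------------------------------------------------------
# grid construction


def _heavy(s):
    mask = s.heavy_mask
    return s.coords[mask], s.element[mask]


def build_grid(s, cfg: DetectionConfig | None = None,
               bounds: tuple | None = None) -> SiteGrid:
    """Lay the grid and flag points inside the receptor vdW envelope.

    ``bounds`` optionally restricts the grid to a cartesian box
    ``(lo, hi)`` (used when re-scoring a known pocket region); the receptor
    margin rule applies otherwise.
    """
    cfg = cfg or DetectionConfig()
    xyz, elements = _heavy(s)
    if len(xyz) == 0:
        raise ValueError("structure has no heavy atoms")
    if bounds is None:
        lo = xyz.min(axis=0) - cfg.margin
        hi = xyz.max(axis=0) + cfg.margin
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    dims = tuple(int(np.floor((hi[k] - lo[k]) / cfg.grid_spacing)) + 1 for k in range(3))
    n = int(np.prod(dims))
    if n > cfg.max_points:
        suggested = cfg.grid_spacing * (n / cfg.max_points) ** (1.0 / 3.0)
        raise MemoryBudgetError(
            f"grid of {n} points exceeds budget {cfg.max_points}; "
            f"try grid_spacing >= {suggested:.2f} A"
        )
    inside = np.zeros(dims, dtype=bool)
    radii = atom_vdw_radii(elements)
    _mark_inside(inside, lo, cfg.grid_spacing, xyz, radii)
    return SiteGrid(origin=lo, spacing=cfg.grid_spacing, dims=dims, inside_receptor=inside)


def _subbox(origin, spacing, dims, center, reach):
    i0 = np.maximum(np.ceil((center - reach - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.floor((center + reach - origin) / spacing).astype(int),
                    np.array(dims) - 1)
    return i0, i1


def _mark_inside(inside, origin, spacing, xyz, radii):
    dims = inside.shape
    for a in range(len(xyz)):
        r = radii[a]
        i0, i1 = _subbox(origin, spacing, dims, xyz[a], r)
        if np.any(i0 > i1):
            continue
        ax = origin[0] + spacing * np.arange(i0[0], i1[0] + 1) - xyz[a, 0]
        ay = origin[1] + spacing * np.arange(i0[1], i1[1] + 1) - xyz[a, 1]
        az = origin[2] + spacing * np.arange(i0[2], i1[2] + 1) - xyz[a, 2]
        d2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        sub = inside[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
        sub |= d2 <= r * r


# ---------------------------------------------------------------------------
# vdW probe energy


def vdw_energy_field(g: SiteGrid, s, cfg: DetectionConfig | None = None) -> SiteGrid:
    """6-12 probe interaction energy at every outside point (kcal/mol)."""
    cfg = cfg or DetectionConfig()
    xyz, elements = _heavy(s)
    rmin, eps = probe_pair_params(elements)
    energy = np.zeros(g.dims, dtype=float)
    cutoff = cfg.vdw_cutoff
    for a in range(len(xyz)):
        i0, i1 = _subbox(g.origin, g.spacing, g.dims, xyz[a], cutoff)
        if np.any(i0 > i1):
            continue
        ax = g.origin[0] + g.spacing * np.arange(i0[0], i1[0] + 1) - xyz[a, 0]
        ay = g.origin[1] + g.spacing * np.arange(i0[1], i1[1] + 1) - xyz[a, 1]
        az = g.origin[2] + g.spacing * np.arange(i0[2], i1[2] + 1) - xyz[a, 2]
        d2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        np.maximum(d2, 1e-4, out=d2)
        inv6 = (rmin[a] ** 2 / d2) ** 3
        e = eps[a] * (inv6 * inv6 - 2.0 * inv6)
        e[d2 > cutoff * cutoff] = 0.0
        energy[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] += e
    energy[g.inside_receptor] = np.inf
    g.vdw_energy = energy
    return g


# ---------------------------------------------------------------------------
# enclosure


@njit(cache=True)
def _march_kernel(pts, rays, inside, origin, inv_h, maxdist, step):
    """Fraction of rays whose first entry into the receptor envelope
    (occupancy grid, marched at ``step`` A) lies within ``maxdist``."""
    n = pts.shape[0]
    nr = rays.shape[0]
    nx, ny, nz = inside.shape
    nsteps = int(maxdist / step)
    out = np.empty(n)
    for i in range(n):
        px, py, pz = pts[i, 0], pts[i, 1], pts[i, 2]
        hits = 0
        for r in range(nr):
            dx, dy, dz = rays[r, 0], rays[r, 1], rays[r, 2]
            t = step
            for _ in range(nsteps):
                x = px + t * dx
                y = py + t * dy
                z = pz + t * dz
                ix = int((x - origin[0]) * inv_h + 0.5)
                if ix < 0 or ix >= nx:
                    break
                iy = int((y - origin[1]) * inv_h + 0.5)
                if iy < 0 or iy >= ny:
                    break
                iz = int((z - origin[2]) * inv_h + 0.5)
                if iz < 0 or iz >= nz:
                    break
                if inside[ix, iy, iz]:
                    hits += 1
                    break
                t += step
        out[i] = hits / nr
    return out


@njit(cache=True)
def _enclosure_kernel(pts, rays, nbr_idx, nbr_ptr, atom_xyz, atom_rad, maxdist):
    n = pts.shape[0]
    nr = rays.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = pts[i, 0], pts[i, 1], pts[i, 2]
        hits = 0
        for r in range(nr):
            dx, dy, dz = rays[r, 0], rays[r, 1], rays[r, 2]
            tmin = 1.0e30
            for k in range(nbr_ptr[i], nbr_ptr[i + 1]):
                a = nbr_idx[k]
                cx = atom_xyz[a, 0] - px
                cy = atom_xyz[a, 1] - py
                cz = atom_xyz[a, 2] - pz
                b = dx * cx + dy * cy + dz * cz
                if b <= 0.0:
                    continue
                c2 = cx * cx + cy * cy + cz * cz - atom_rad[a] * atom_rad[a]
                disc = b * b - c2
                if disc > 0.0:
                    t = b - np.sqrt(disc)
                    if 0.0 < t < tmin:
                        tmin = t
            if tmin <= maxdist:
                hits += 1
        out[i] = hits / nr
    return out


def enclosure_at_points(points: np.ndarray, s, cfg: DetectionConfig) -> np.ndarray:
    """Enclosure fraction at arbitrary cartesian points by exact analytic
    ray-sphere intersection (utility; the grid field uses envelope
    marching, see :func:`enclosure_field`)."""
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.zeros(0)
    xyz, elements = _heavy(s)
    radii = atom_vdw_radii(elements)
    rays = fibonacci_sphere(cfg.n_rays)
    tree = cKDTree(xyz)
    reach = cfg.maxdist + float(radii.max(initial=DEFAULT_VDW_RADIUS))
    neighbours = tree.query_ball_point(points, reach)
    ptr = np.zeros(len(points) + 1, dtype=np.int64)
    for i, nb in enumerate(neighbours):
        ptr[i + 1] = ptr[i] + len(nb)
    idx = np.empty(ptr[-1], dtype=np.int64)
    for i, nb in enumerate(neighbours):
        idx[ptr[i]:ptr[i + 1]] = sorted(nb)
    return _enclosure_kernel(points, rays, idx, ptr, xyz, radii, cfg.maxdist)


#: ray-march step along enclosure rays (A)
MARCH_STEP = 0.25


def enclosure_field(g: SiteGrid, s, cfg: DetectionConfig | None = None,
                    candidates: np.ndarray | None = None) -> SiteGrid:
    """Enclosure fraction at candidate points (default: favourable-energy
    outside points); all other points are left at zero.

    Rays are marched at 0.25 A steps against the occupancy grid; the first
    step landing inside the receptor envelope is the surface intersection.
    A ray leaving the grid cannot strike the receptor (the grid fully
    contains it) and is dropped early.
    """
    cfg = cfg or DetectionConfig()
    if candidates is None:
        if g.vdw_energy is None:
            raise ValueError("vdw_energy_field must run before enclosure_field")
        candidates = (~g.inside_receptor) & (g.vdw_energy <= -cfg.maxvdw)
    enc = np.zeros(g.dims, dtype=float)
    pts = g.point_coords(candidates)
    if len(pts):
        rays = fibonacci_sphere(cfg.n_rays)
        enc[candidates] = _march_kernel(
            pts, rays, g.inside_receptor, g.origin,
            1.0 / g.spacing, cfg.maxdist, MARCH_STEP,
        )
    g.enclosure_fraction = enc
    return g


# ---------------------------------------------------------------------------
# phobic / philic potentials


_CHARGED_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}

_APOLAR_CACHE: dict[str, frozenset] = {}


def _carbon_polarity_names(res_name: str):
    """(apolar carbon names, all template carbon names) of a residue.

    A carbon is apolar when it has no covalent bond to N or O in the ideal
    component template.  Unknown residues yield empty sets; carbons absent
    from the template fall back to the apolar default.
    """
    if res_name in _APOLAR_CACHE:
        return _APOLAR_CACHE[res_name]
    apolar, carbons = set(), set()
    try:
        import biotite.structure.info as info

        tpl = info.residue(res_name)
    except Exception:
        tpl = None
    if tpl is not None and tpl.bonds is not None:
        names = list(tpl.atom_name)
        elems = list(tpl.element)
        adj = {i: set() for i in range(len(names))}
        for a, b, _ in tpl.bonds.as_array():
            adj[int(a)].add(int(b))
            adj[int(b)].add(int(a))
        for i, (n, e) in enumerate(zip(names, elems)):
            if e != "C":
                continue
            carbons.add(str(n))
            if all(elems[j] not in ("N", "O") for j in adj[i]):
                apolar.add(str(n))
    result = (frozenset(apolar), frozenset(carbons))
    _APOLAR_CACHE[res_name] = result
    return result


def _polarity_classes(s):
    """(polar_mask, polar_weight, apolar_mask) over heavy atoms."""
    mask = s.heavy_mask
    elements = s.element[mask]
    res_names = s.res_name[mask]
    atom_names = s.atom_name[mask]

    polar = np.zeros(len(elements), dtype=bool)
    weight = np.ones(len(elements))
    apolar = np.zeros(len(elements), dtype=bool)
    known = {}
    for i, (e, rn, an) in enumerate(zip(elements, res_names, atom_names)):
        e, rn, an = str(e), str(rn), str(an)
        if e in ("N", "O"):
            polar[i] = True
            if (rn, an) in _CHARGED_ATOMS:
                weight[i] = 2.0
        elif e == "S" and rn not in ("CYS", "MET"):
            polar[i] = True
        elif e in ("F", "CL", "BR", "I"):
            apolar[i] = True   # halogens: hydrophobic, no H-bonding
        elif e == "C":
            if rn not in known:
                known[rn] = _carbon_polarity_names(rn)
            apolar_names, carbon_names = known[rn]
            # template-based where the atom name is known; apolar otherwise
            apolar[i] = an in apolar_names or an not in carbon_names
    return polar, weight, apolar


def _kernel_sum(g, coords, weights, radius, out, mask):
    """Accumulate sum_j w_j (1 - r/radius)^2 over atoms within ``radius``."""
    for a in range(len(coords)):
        i0, i1 = _subbox(g.origin, g.spacing, g.dims, coords[a], radius)
        if np.any(i0 > i1):
            continue
        ax = g.origin[0] + g.spacing * np.arange(i0[0], i1[0] + 1) - coords[a, 0]
        ay = g.origin[1] + g.spacing * np.arange(i0[1], i1[1] + 1) - coords[a, 1]
        az = g.origin[2] + g.spacing * np.arange(i0[2], i1[2] + 1) - coords[a, 2]
        d = np.sqrt(
            ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        )
        k = weights[a] * np.maximum(0.0, 1.0 - d / radius) ** 2
        out[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1] += k


def phobic_philic_fields(g: SiteGrid, s, cfg: DetectionConfig | None = None) -> SiteGrid:
    """Hydrophobic and hydrophilic contact potentials at all grid points.

    With ``modphobic = 0`` the phobic potential is the raw kernel sum with
    no attenuation in solvent-open regions.
    """
    cfg = cfg or DetectionConfig()
    heavy = s.heavy_mask
    coords = s.coords[heavy]
    polar, weight, apolar = _polarity_classes(s)
    phobic = np.zeros(g.dims, dtype=float)
    philic = np.zeros(g.dims, dtype=float)
    _kernel_sum(g, coords[apolar], np.ones(int(apolar.sum())),
                cfg.polar_radius, phobic, None)
    _kernel_sum(g, coords[polar], weight[polar], cfg.polar_radius, philic, None)
    g.phobic_potential = phobic / PHOBIC_REFERENCE_MEAN
    g.philic_potential = philic / PHILIC_REFERENCE_MEAN
    return g


# ---------------------------------------------------------------------------
# site points


def mark_site_points(g: SiteGrid, cfg: DetectionConfig | None = None) -> SiteGrid:
    """Flag points that are outside, enclosed, and energetically favourable."""
    cfg = cfg or DetectionConfig()
    if g.vdw_energy is None or g.enclosure_fraction is None:
        raise ValueError("vdw and enclosure fields must be computed first")
    g.is_site_point = (
        (~g.inside_receptor)
        & (g.enclosure_fraction >= cfg.enclosure_min)
        & (g.vdw_energy <= -cfg.maxvdw)
    )
    return g


def detect_fields(s, cfg: DetectionConfig | None = None,
                  bounds: tuple | None = None) -> SiteGrid:
    """Convenience pipeline: grid -> vdW -> enclosure -> phobic/philic -> mark."""
    cfg = cfg or DetectionConfig()
    g = build_grid(s, cfg, bounds=bounds)
    vdw_energy_field(g, s, cfg)
    enclosure_field(g, s, cfg)
    phobic_philic_fields(g, s, cfg)
    mark_site_points(g, cfg)
    return g
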