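"""Clustering of site points into ranked candidate sites.

Site points are first filtered by local support (a point needs at least
``nthresh`` other site points within ``neighbor_radius``), then clustered
by single linkage with joining distance ``dthresh`` -- two groups merge
when their closest points are nearer than ``dthresh``.  Clusters below
``mingroup`` points are discarded and the survivors are ranked by site-point
count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .site_grid import DetectionConfig, SiteGrid

__all__ = [
    "Site",
    "filter_supported_points",
    "cluster_sites",
    "rank_sites",
    "site_volume",
    "find_sites",
]


@dataclass
class Site:
    """A cluster of site points with geometric descriptors."""

    site_id: int
    points: np.ndarray          # (n, 3) member coordinates, A
    n: int                      # site-point count
    volume: float = 0.0         # A^3
    centroid: np.ndarray = None
    descriptors: object = None  # filled by the descriptors module
    rank: int = 0
    oversized: bool = False     # volume above the drug-like upper bound

    def __post_init__(self):
        if self.centroid is None:
            self.centroid = self.points.mean(axis=0)

    def to_json(self) -> dict:
        out = {
            "site_id": int(self.site_id),
            "n": int(self.n),
            "volume": round(float(self.volume), 1),
            "centroid": [round(float(x), 3) for x in self.centroid],
            "rank": int(self.rank),
            "oversized": bool(self.oversized),
        }
        if self.descriptors is not None:
            out["descriptors"] = self.descriptors.to_json()
        return out


def filter_supported_points(points: np.ndarray, cfg: DetectionConfig | None = None) -> np.ndarray:
    """Retain points having >= ``nthresh`` other points within
    ``neighbor_radius``; the filter is applied once (not iterated)."""
    cfg = cfg or DetectionConfig()
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return points
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, cfg.neighbor_radius, return_length=True)
    return points[(counts - 1) >= cfg.nthresh]


def cluster_sites(points: np.ndarray, cfg: DetectionConfig | None = None) -> list:
    """Single-linkage clusters at joining distance ``dthresh``.

    Returns clusters with >= ``mingroup`` points sorted by descending size.
    """
    cfg = cfg or DetectionConfig()
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(cfg.dthresh, output_type="ndarray")
    n = len(points)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    sites = []
    for lab in np.unique(labels):
        member = points[labels == lab]
        if len(member) < cfg.mingroup:
            continue
        sites.append(Site(site_id=0, points=member, n=len(member)))
    sites.sort(key=lambda s: (-s.n, tuple(np.round(s.centroid, 6))))
    for i, s in enumerate(sites):
        s.site_id = i + 1
    return sites


def rank_sites(sites: list, cfg: DetectionConfig | None = None) -> list:
    """Top ``max_sites`` sites by point count (ties: larger volume, then
    lower lexicographic centroid)."""
    cfg = cfg or DetectionConfig()
    ordered = sorted(
        sites,
        key=lambda s: (-s.n, -float(s.volume), tuple(np.round(s.centroid, 6))),
    )
    top = ordered[: cfg.max_sites]
    for i, s in enumerate(top):
        s.rank = i + 1
    return top


def site_volume(site: Site, cfg: DetectionConfig | None = None,
                grid: SiteGrid | None = None) -> float:
    """Site volume in A^3.

    Without grid context the member points themselves are the occupied
    cells (``n * spacing^3``).  With the detection grid available, the
    volume is that of the site's *enclosed void*: every grid cell outside
    the receptor envelope that lies within ``volume_reach`` of a member
    point and is itself reasonably enclosed (enclosure >= the site-point
    threshold, evaluated on demand).  Site points occupy the attractive
    core of a pocket, offset from the walls by roughly the probe contact
    distance; the reach term restores the wall-adjacent void so that the
    measure approximates the geometric cavity volume, while the enclosure
    requirement keeps it from spilling past the pocket mouth or onto the
    rough outer surface.
    """
    cfg = cfg or DetectionConfig()
    h = cfg.grid_spacing
    if grid is None:
        cells = {tuple(c) for c in np.rint(site.points / h).astype(int)}
        return len(cells) * h**3
    reach = cfg.volume_reach
    lo = np.maximum(
        np.floor((site.points.min(axis=0) - reach - grid.origin) / grid.spacing).astype(int),
        0,
    )
    hi = np.minimum(
        np.ceil((site.points.max(axis=0) + reach - grid.origin) / grid.spacing).astype(int),
        np.array(grid.dims) - 1,
    )
    sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
    sub = ~grid.inside_receptor[sl]
    idx = np.argwhere(sub) + lo
    coords = grid.origin[None, :] + idx * grid.spacing
    tree = cKDTree(site.points)
    d, _ = tree.query(coords, k=1, distance_upper_bound=reach)
    near = np.isfinite(d)
    if not near.any():
        return 0.0
    from .site_grid import _march_kernel, fibonacci_sphere

    rays = fibonacci_sphere(cfg.n_rays)
    enc = _march_kernel(
        np.ascontiguousarray(coords[near]), rays, grid.inside_receptor,
        grid.origin, 1.0 / grid.spacing, cfg.maxdist, 0.25,
    )
    return float(np.sum(enc >= cfg.enclosure_min) * grid.spacing**3)


def find_sites(grid: SiteGrid, cfg: DetectionConfig | None = None) -> list:
    """Full site extraction from a computed grid: support filter, single
    linkage, volume, drug-size flagging, top-``max_sites`` ranking."""
    cfg = cfg or DetectionConfig()
    if grid.is_site_point is None:
        raise ValueError("site points not marked")
    pts = grid.point_coords(grid.is_site_point)
    pts = filter_supported_points(pts, cfg)
    sites = cluster_sites(pts, cfg)
    for s in sites:
        s.volume = site_volume(s, cfg, grid=grid)
        s.oversized = s.volume > 800.0
    return rank_sites(sites, cfg)


def sites_to_json(sites: list, path=None):
    payload = [s.to_json() for s in sites]
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload
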