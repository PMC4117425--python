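"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force (dense random rays,
O(n^2) neighbour counts, union-find over the full distance matrix) so that
they share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np

from flexsite.site_grid import atom_vdw_radii


def dense_ray_enclosure(point, s, maxdist=10.0, n_rays=1_000_000, seed=123,
                        chunk=20_000):
    """Enclosure fraction by analytic first-hit of dense random rays."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_rays, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    mask = s.heavy_mask
    xyz = s.coords[mask] - np.asarray(point, dtype=float)
    rad = atom_vdw_radii(s.element[mask])
    keep = np.linalg.norm(xyz, axis=1) <= maxdist + rad.max()
    xyz, rad = xyz[keep], rad[keep]
    c2 = (xyz**2).sum(axis=1)[None, :] - rad[None, :] ** 2
    hits = np.zeros(n_rays, dtype=bool)
    for i0 in range(0, n_rays, chunk):
        d = v[i0:i0 + chunk]
        b = d @ xyz.T
        disc = b * b - c2
        ok = (b > 0) & (disc > 0)
        t = np.where(ok, b - np.sqrt(np.maximum(disc, 0.0)), np.inf)
        t[t <= 0] = np.inf
        hits[i0:i0 + chunk] = t.min(axis=1) <= maxdist
    return float(hits.mean())


def brute_force_neighbor_filter(points, radius, nthresh):
    """O(n^2) support filter: keep points with >= nthresh others in range."""
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    counts = (d <= radius).sum(axis=1) - 1
    return points[counts >= nthresh]


def union_find_clusters(points, linkage):
    """Single-linkage clusters via explicit union-find on all pairs."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= linkage:
                union(i, j)
    labels = np.array([find(i) for i in range(n)])
    return [frozenset(np.flatnonzero(labels == lab).tolist())
            for lab in np.unique(labels)]


def brute_force_inside(points, xyz, radii):
    """Per-point inside-envelope flag by direct distance check."""
    out = np.zeros(len(points), dtype=bool)
    for a in range(len(xyz)):
        out |= np.linalg.norm(points - xyz[a], axis=1) <= radii[a]
    return out


def kernel_sum(point, coords, weights, radius):
    """Direct (1 - r/radius)^2 kernel sum at one point."""
    d = np.linalg.norm(coords - np.asarray(point, dtype=float), axis=1)
    k = np.maximum(0.0, 1.0 - d / radius) ** 2
    return float((weights * k).sum())
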