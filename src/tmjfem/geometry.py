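"""Triangle-mesh geometry kernels: closest-point queries, voxelization, STL I/O.

These are small exact kernels used by the segmentation stage (surface
deviation, CAD alignment) and the phantom generator (rasterizing the
prosthesis surface into the voxel grid).  Closest-point distances are
point-to-triangle, not point-to-vertex: candidate triangles are pruned with a
k-d tree and then measured exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import Mask, TriSurface

__all__ = [
    "closest_point_on_surface",
    "voxelize_surface",
    "read_stl",
    "write_stl",
]


def _closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                             c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a,b,c) to p, all arrays (n, 3), row-matched.

    Region-based projection (Voronoi regions of the triangle), fully
    vectorized; exact up to floating point.
    """
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    t = np.where(denom > 0, d1[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + t[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    t = np.where(denom > 0, d2[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + t[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    t = np.where(denom > 0, (d4[m] - d3[m]) / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(denom != 0, denom, 1.0)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


def closest_point_on_surface(points: np.ndarray, surface: TriSurface):
    """Exact closest point on a triangle mesh for each query point.

    Returns ``(distances, closest_points, face_indices)``.  A k-d tree over
    mesh vertices supplies an upper bound, a second tree over triangle
    centroids collects every triangle that could beat it, and the survivors
    are measured exactly — so the result equals the brute-force scan.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if surface.n_faces == 0:
        raise ValueError("target surface has no triangles")
    tri = surface.triangles()
    n_tri = len(tri)

    if n_tri <= 64 or len(pts) * n_tri <= 2_000_000:
        # brute force: evaluate every (point, triangle) pair
        P = np.repeat(pts, n_tri, axis=0)
        A = np.tile(tri[:, 0], (len(pts), 1))
        B = np.tile(tri[:, 1], (len(pts), 1))
        C = np.tile(tri[:, 2], (len(pts), 1))
        cp = _closest_point_triangles(P, A, B, C).reshape(len(pts), n_tri, 3)
        d2 = np.sum((cp - pts[:, None, :]) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        return np.sqrt(d2[rows, idx]), cp[rows, idx], idx

    vert_tree = cKDTree(surface.vertices)
    upper, _ = vert_tree.query(pts)
    centroids = tri.mean(axis=1)
    # max centroid-to-corner distance bounds how far a triangle's nearest
    # point can be from its centroid
    r_tri = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    cent_tree = cKDTree(centroids)
    cand = cent_tree.query_ball_point(pts, upper + r_tri + 1e-12)

    counts = np.fromiter((len(c) for c in cand), dtype=np.int64, count=len(pts))
    flat = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
    prow = np.repeat(np.arange(len(pts)), counts)
    cp = _closest_point_triangles(pts[prow], tri[flat, 0], tri[flat, 1],
                                  tri[flat, 2])
    d2 = np.sum((cp - pts[prow]) ** 2, axis=1)

    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    dist = np.empty(len(pts))
    nearest = np.empty((len(pts), 3))
    faces = np.empty(len(pts), dtype=np.int64)
    for i in range(len(pts)):
        s, e = starts[i], starts[i] + counts[i]
        j = s + int(np.argmin(d2[s:e]))
        dist[i] = np.sqrt(d2[j])
        nearest[i] = cp[j]
        faces[i] = flat[j]
    return dist, nearest, faces


def voxelize_surface(surface: TriSurface, shape, spacing, origin,
                     name: str = "") -> Mask:
    """Rasterize a closed triangle surface into a voxel mask.

    A voxel is inside when its centre is inside the surface, decided by
    parity of triangle crossings along the +z grid column through the voxel
    centre.  Grid rays are nudged by a tiny irrational offset so they never
    pass exactly through mesh edges or vertices.
    """
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    tri = surface.triangles()

    eps = 1e-6 * float(spacing.min())
    xs = origin[0] + spacing[0] * np.arange(nx) + eps * np.sqrt(2.0)
    ys = origin[1] + spacing[1] * np.arange(ny) + eps * np.sqrt(3.0)
    zs = origin[2] + spacing[2] * np.arange(nz)

    mask = np.zeros((nx, ny, nz), dtype=bool)
    # crossings per (ix, iy) column
    from collections import defaultdict
    crossings = defaultdict(list)

    for (a, b, c) in tri:
        det = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if det == 0.0:
            continue  # triangle vertical w.r.t. z-rays: measure-zero crossing
        lo_x = np.searchsorted(xs, min(a[0], b[0], c[0]))
        hi_x = np.searchsorted(xs, max(a[0], b[0], c[0]), side="right")
        lo_y = np.searchsorted(ys, min(a[1], b[1], c[1]))
        hi_y = np.searchsorted(ys, max(a[1], b[1], c[1]), side="right")
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        gx = xs[lo_x:hi_x]
        gy = ys[lo_y:hi_y]
        X, Y = np.meshgrid(gx, gy, indexing="ij")
        l2 = ((X - a[0]) * (c[1] - a[1]) - (Y - a[1]) * (c[0] - a[0])) / det
        l3 = ((b[0] - a[0]) * (Y - a[1]) - (b[1] - a[1]) * (X - a[0])) / det
        l1 = 1.0 - l2 - l3
        inside = (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        if not inside.any():
            continue
        zhit = l1 * a[2] + l2 * b[2] + l3 * c[2]
        ii, jj = np.nonzero(inside)
        for i, j, z in zip(ii + lo_x, jj + lo_y, zhit[inside]):
            crossings[(int(i), int(j))].append(float(z))

    for (i, j), zlist in crossings.items():
        zarr = np.sort(np.asarray(zlist))
        if len(zarr) % 2 != 0:
            # should not occur for a watertight surface and jittered rays
            continue
        counts = np.searchsorted(zarr, zs, side="left")
        mask[i, j, :] = (counts % 2) == 1
    return Mask(mask, name=name, spacing=spacing, origin=origin)


def read_stl(path) -> TriSurface:
    import trimesh
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    return TriSurface.from_trimesh(mesh)


def write_stl(surface: TriSurface, path, ascii: bool = False) -> None:
    mesh = surface.to_trimesh()
    if ascii:
        with open(path, "w") as fh:
            fh.write(mesh.export(file_type="stl_ascii"))
    else:
        mesh.export(str(path), file_type="stl")
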