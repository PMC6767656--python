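"""Triangular disk meshes for the 2D Helmholtz solver.

The problem domain is a disk of radius ``radius`` (cm) centred at the
origin.  Nodes are laid out on concentric rings with spacing close to the
requested maximum edge length and triangulated with Delaunay; the result
is a conforming mesh of near-uniform element size whose outermost ring is
the absorbing boundary.  Linear (P1) basis functions are assumed
throughout the package.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay


@dataclasses.dataclass
class Mesh:
    points: np.ndarray      # (N, 2) node coordinates, cm
    simplices: np.ndarray   # (M, 3) triangle connectivity
    boundary_nodes: np.ndarray  # indices of nodes on the outer circle
    radius: float           # outer radius, cm
    h: float                # nominal edge length, cm
    _delaunay: Delaunay = dataclasses.field(repr=False, default=None)

    @property
    def n_nodes(self):
        return self.points.shape[0]

    @property
    def n_triangles(self):
        return self.simplices.shape[0]

    def find_simplex(self, pts):
        return self._delaunay.find_simplex(np.asarray(pts, dtype=float))

    def interp_matrix(self, pts):
        """Sparse (P, N) barycentric interpolation matrix for query points.

        Rows for points outside the mesh are left empty (all zeros).
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        simp = self._delaunay.find_simplex(pts)
        inside = simp >= 0
        rows, cols, vals = [], [], []
        if inside.any():
            s = simp[inside]
            T = self._delaunay.transform[s]
            b = np.einsum("pij,pj->pi", T[:, :2, :], pts[inside] - T[:, 2, :])
            bary = np.column_stack([b, 1.0 - b.sum(axis=1)])
            nodes = self.simplices[s]
            prow = np.flatnonzero(inside)
            rows = np.repeat(prow, 3)
            cols = nodes.ravel()
            vals = bary.ravel()
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(pts.shape[0], self.n_nodes)
        )

    def element_centroids(self):
        return self.points[self.simplices].mean(axis=1)

    def sample_image(self, grid, pixel_size, fill, at="nodes"):
        """Values sampled from the pixel each node (or centroid) falls in.

        The image is centred at the origin; points outside the image take
        ``fill``.  ``at="elements"`` samples at triangle centroids, which
        represents sharp material interfaces better in the FEM matrices.
        """
        grid = np.asarray(grid)
        pts = self.points if at == "nodes" else self.element_centroids()
        m, n = grid.shape
        col = np.floor(pts[:, 0] / pixel_size + n / 2.0).astype(int)
        row = np.floor(pts[:, 1] / pixel_size + m / 2.0).astype(int)
        ok = (row >= 0) & (row < m) & (col >= 0) & (col < n)
        out = np.full(pts.shape[0], fill, dtype=grid.dtype)
        out[ok] = grid[row[ok], col[ok]]
        return out


def build_disk_mesh(radius, max_edge) -> Mesh:
    """Concentric-ring Delaunay mesh of a disk with edge length <= max_edge.

    Raises if the edge bound is too coarse to resolve the disk (fewer than
    three rings).
    """
    n_rings = int(np.ceil(radius / max_edge))
    if n_rings < 3:
        raise ValueError(
            f"max_edge {max_edge} too coarse for a disk of radius {radius}"
        )
    h = radius / n_rings
    pts = [np.zeros((1, 2))]
    ring_start = None
    for i in range(1, n_rings + 1):
        r = i * h
        n_i = max(8, int(np.ceil(2 * np.pi * r / h)))
        offs = (i % 2) * np.pi / n_i
        th = offs + 2 * np.pi * np.arange(n_i) / n_i
        ring = np.column_stack([r * np.cos(th), r * np.sin(th)])
        if i == n_rings:
            ring_start = sum(p.shape[0] for p in pts)
        pts.append(ring)
    points = np.vstack(pts)
    tri = Delaunay(points)
    boundary = np.arange(ring_start, points.shape[0])
    return Mesh(
        points=points,
        simplices=tri.simplices.copy(),
        boundary_nodes=boundary,
        radius=float(radius),
        h=float(h),
        _delaunay=tri,
    )


def triangle_geometry(mesh: Mesh):
    """Per-triangle areas and P1 basis gradients.

    Returns (areas (M,), grads (M, 3, 2)) with grads[t, i] the constant
    gradient of the basis function of local node i on triangle t.
    """
    p = mesh.points[mesh.simplices]  # (M, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    area = 0.5 * np.abs(det)
    # gradient of barycentric coordinate i: perpendicular of opposite edge
    grads = np.empty((p.shape[0], 3, 2))
    for i in range(3):
        a = p[:, (i + 1) % 3]
        b = p[:, (i + 2) % 3]
        edge = b - a
        grads[:, i, 0] = -edge[:, 1]
        grads[:, i, 1] = edge[:, 0]
    grads /= det[:, None, None]
    # ensure orientation-independent sign: grad_i points toward node i
    return area, grads


def boundary_edges(mesh: Mesh):
    """Consecutive node pairs along the outer ring, ordered by angle."""
    b = mesh.boundary_nodes
    th = np.arctan2(mesh.points[b, 1], mesh.points[b, 0])
    order = b[np.argsort(th)]
    return np.column_stack([order, np.roll(order, -1)])
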