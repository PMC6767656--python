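"""2D TM scalar-Helmholtz FEM forward solver and synthetic data generation.

A transverse-magnetic line source reduces Maxwell's equations to the scalar
Helmholtz equation for the out-of-plane electric field.  The weak form on
linear triangles with a first-order absorbing boundary condition on the
outer circle gives the complex-symmetric system

    (K - M[k^2] + j*k_b*B) u = s,

where K is the stiffness matrix, M[k^2] the mass matrix weighted by the
local squared wavenumber, B the boundary mass matrix and k_b the
(complex) background wavenumber.  A unit line source at r_s contributes
its nodal interpolation weights to the right-hand side, which makes the
discrete solution converge to the outgoing cylindrical wave
-(j/4) * H0^(2)(k|r - r_s|) in a homogeneous medium.

Synthetic scattered-field data is the total-field solve with the phantom
permittivity minus the incident-field solve with the background map; the
contrast-source operator used by the inversion is never used to generate
data (inverse-crime mitigation), and data can be generated on a finer
mesh than the inversion uses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import h2vp, hankel2, jv, jvp

from .constants import DEFAULT_FREQUENCY, wavenumber, wavelength
from .mesh import Mesh, boundary_edges, build_disk_mesh, triangle_geometry

#: outer (absorbing) boundary radius as a multiple of the measurement radius
OMEGA_OVER_S = 1.5


@dataclasses.dataclass
class AcquisitionGeometry:
    """Circular multistatic acquisition around a square imaging domain D."""

    frequency: float                 # Hz
    tx_positions: np.ndarray         # (T, 2) cm
    rx_positions: np.ndarray         # (R, 2) cm
    background_eps: complex          # immersion-medium relative permittivity
    domain_half_width: float         # D is the square [-d, d]^2, cm
    s_radius: float                  # measurement-circle radius, cm

    def __post_init__(self):
        for pts, name in ((self.tx_positions, "tx"), (self.rx_positions, "rx")):
            inside = np.all(np.abs(pts) <= self.domain_half_width, axis=1)
            if inside.any():
                raise ValueError(f"{name} positions must lie strictly outside D")

    @property
    def n_tx(self):
        return self.tx_positions.shape[0]

    @property
    def n_rx(self):
        return self.rx_positions.shape[0]

    @property
    def omega_radius(self):
        return OMEGA_OVER_S * self.s_radius

    @property
    def k_background(self):
        return wavenumber(self.frequency, self.background_eps)

    @classmethod
    def circular(cls, domain_half_width, frequency=DEFAULT_FREQUENCY,
                 n_tx=24, n_rx=24, s_radius=None, background_eps=23.0 - 1.0j):
        """Equally spaced transceivers on a circle enclosing D.

        Receivers are rotated half a step relative to transmitters so no
        receiver coincides with an active source.
        """
        if s_radius is None:
            s_radius = 1.05 * np.sqrt(2.0) * domain_half_width
        th_t = 2 * np.pi * np.arange(n_tx) / n_tx
        th_r = 2 * np.pi * (np.arange(n_rx) + 0.5) / n_rx
        tx = s_radius * np.column_stack([np.cos(th_t), np.sin(th_t)])
        rx = s_radius * np.column_stack([np.cos(th_r), np.sin(th_r)])
        return cls(frequency=frequency, tx_positions=tx, rx_positions=rx,
                   background_eps=complex(background_eps),
                   domain_half_width=float(domain_half_width),
                   s_radius=float(s_radius))


@dataclasses.dataclass
class ScatterDataset:
    """Measured scattered fields f_t: one row per transmitter."""

    f: np.ndarray                    # (T, R) complex
    geometry: AcquisitionGeometry
    noise_level: float = 0.0


def build_mesh(geometry: AcquisitionGeometry, eps_max, max_edge_frac=0.1) -> Mesh:
    """Disk mesh of the problem domain resolving the shortest wavelength.

    ``eps_max`` is the largest real permittivity expected anywhere (the
    highest-permittivity tissue); the edge bound is
    ``max_edge_frac * lambda_min``.
    """
    lam_min = wavelength(geometry.frequency, np.real(eps_max))
    return build_disk_mesh(geometry.omega_radius, max_edge_frac * lam_min)


def assemble_matrices(mesh: Mesh):
    """Stiffness K, unit mass templates and boundary mass B (all sparse).

    Returns (K, rows/cols/elem_areas needed for weighted mass assembly, B).
    The weighted mass matrix for a nodal coefficient field c uses the
    element-mean of c.
    """
    area, grads = triangle_geometry(mesh)
    tris = mesh.simplices
    M = tris.shape[0]
    ii = np.repeat(tris, 3, axis=1).ravel()          # (M*9,)
    jj = np.tile(tris, (1, 3)).ravel()
    ke = np.einsum("tid,tjd->tij", grads, grads) * area[:, None, None]
    K = sparse.coo_matrix((ke.ravel(), (ii, jj)),
                          shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()

    # consistent P1 mass template: area/12 * (1 + delta_ij)
    me = (np.ones((3, 3)) + np.eye(3)) / 12.0
    mass_entries = (area[:, None, None] * me[None, :, :]).ravel()

    edges = boundary_edges(mesh)
    lengths = np.linalg.norm(
        mesh.points[edges[:, 0]] - mesh.points[edges[:, 1]], axis=1
    )
    be = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    bi = np.repeat(edges, 2, axis=1).ravel()
    bj = np.tile(edges, (1, 2)).ravel()
    bv = (lengths[:, None, None] * be[None, :, :]).ravel()
    B = sparse.coo_matrix((bv, (bi, bj)),
                          shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return K, (ii, jj, mass_entries), B


def weighted_mass(mesh: Mesh, mass_template, coeff_elem):
    """Mass matrix weighted by a per-element coefficient."""
    ii, jj, entries = mass_template
    vals = entries * np.repeat(np.asarray(coeff_elem), 9)
    return sparse.coo_matrix((vals, (ii, jj)),
                             shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()


class FemSystem:
    """Factorized Helmholtz system for one permittivity map on one mesh.

    ``eps`` may be given per mesh node (averaged onto elements) or per
    triangle (e.g. sampled at element centroids, which represents sharp
    material interfaces more faithfully).  The absorbing boundary uses the
    first-order condition with the curvature correction for a circular
    boundary, du/dn = -(j*k_b + 1/(2R)) u.

    The k^2 mass matrix is the half-and-half blend of the consistent and
    row-sum-lumped P1 mass matrices; the blend cancels most of the
    leading-order numerical dispersion of linear triangles, which
    otherwise accumulates as a phase drift across the electrically large
    problem domain.
    """

    #: consistent/lumped mass blend weight (1.0 = fully consistent)
    mass_blend = 0.5

    def __init__(self, mesh: Mesh, geometry: AcquisitionGeometry, eps):
        self.mesh = mesh
        self.geometry = geometry
        eps = np.asarray(eps, dtype=complex)
        if eps.shape == (mesh.n_nodes,):
            eps_elem = np.mean(eps[mesh.simplices], axis=1)
        elif eps.shape == (mesh.n_triangles,):
            eps_elem = eps
        else:
            raise ValueError(
                "eps must be defined on every mesh node or every triangle"
            )
        k0 = 2 * np.pi * geometry.frequency / 2.99792458e10
        self.k2_elem = (k0 ** 2) * eps_elem
        K, self._mass_template, B = assemble_matrices(mesh)
        Mc = weighted_mass(mesh, self._mass_template, self.k2_elem)
        lumped = np.asarray(Mc.sum(axis=1)).ravel()
        th = self.mass_blend
        self.Mk2 = (th * Mc + (1.0 - th) * sparse.diags(lumped)).tocsr()
        kb = geometry.k_background
        A = (K - self.Mk2 + (1j * kb + 0.5 / mesh.radius) * B).tocsc()
        self.A = A
        try:
            self.lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"singular FEM system (n={mesh.n_nodes}): {exc}"
            ) from exc

    def solve(self, rhs, adjoint=False):
        """Solve A u = rhs (or A^H u = rhs); rhs may be (N,) or (N, T)."""
        rhs = np.asarray(rhs, dtype=complex)
        return self.lu.solve(rhs, trans="H" if adjoint else "N")

    def source_vectors(self, points):
        """(N, P) sparse matrix of nodal interpolation weights for unit
        line sources at the given points."""
        return self.mesh.interp_matrix(points).T.tocsc()

    def incident_fields(self, points=None):
        """Fields of unit line sources at each transmitter, (T, N)."""
        pts = self.geometry.tx_positions if points is None else points
        S = np.asarray(self.source_vectors(pts).todense())
        return self.solve(S).T


def line_source_field(k, source, points):
    """Closed-form outgoing 2D line-source field -(j/4) H0^(2)(k r)."""
    r = np.linalg.norm(np.atleast_2d(points) - np.asarray(source), axis=1)
    return -0.25j * hankel2(0, k * r)


def solve_incident(geometry: AcquisitionGeometry, mesh: Mesh, eps_n_nodes):
    """FEM incident fields for every transmitter on the given background.

    For a homogeneous background this converges to the closed-form
    cylindrical wave; for an inhomogeneous numerical background it is the
    field in the presence of that background with no object.
    """
    sys = FemSystem(mesh, geometry, eps_n_nodes)
    return sys.incident_fields()


def forward_scatter(phantom, geometry: AcquisitionGeometry, mesh: Mesh = None,
                    background=None, max_edge_frac=0.1) -> ScatterDataset:
    """Noise-free scattered data: total-field solve minus incident solve.

    Parameters
    ----------
    phantom : Phantom
        Supplies the permittivity image sampled onto the mesh.
    background : None | PriorBackground | complex ndarray
        Background map defining the incident field the data is referenced
        to.  ``None`` means the homogeneous immersion medium; a prior
        background makes the data directly consumable by prior-based CSI.
    """
    if mesh is None:
        mesh = build_mesh(geometry, np.max(phantom.eps_real), max_edge_frac)
    eps_obj = mesh.sample_image(phantom.eps, phantom.pixel_size,
                                geometry.background_eps, at="elements")
    if background is None:
        eps_bg = np.full(mesh.n_triangles, geometry.background_eps, dtype=complex)
    elif hasattr(background, "eps_n"):
        eps_bg = mesh.sample_image(background.eps_n, phantom.pixel_size,
                                   geometry.background_eps, at="elements")
    else:
        bg = np.asarray(background)
        if bg.ndim == 2:
            eps_bg = mesh.sample_image(bg.astype(complex), phantom.pixel_size,
                                       geometry.background_eps, at="elements")
        else:
            eps_bg = bg.astype(complex)

    sys_obj = FemSystem(mesh, geometry, eps_obj)
    sys_bg = FemSystem(mesh, geometry, eps_bg)
    S = np.asarray(sys_obj.source_vectors(geometry.tx_positions).todense())
    Ms = mesh.interp_matrix(geometry.rx_positions)
    e_tot = Ms @ sys_obj.solve(S)       # (R, T)
    e_inc = Ms @ sys_bg.solve(S)
    f = (e_tot - e_inc).T               # (T, R)
    return ScatterDataset(f=f, geometry=geometry, noise_level=0.0)


def add_noise(dataset: ScatterDataset, level, rng) -> ScatterDataset:
    """Additive complex Gaussian noise calibrated to the dataset RMS.

    Each datum receives independent circular Gaussian noise scaled so the
    expected noise RMS equals ``level`` times the RMS of the noise-free
    data over the whole measurement set.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if level == 0:
        return ScatterDataset(f=dataset.f.copy(), geometry=dataset.geometry,
                              noise_level=0.0)
    rng = np.random.default_rng(rng)
    rms = np.sqrt(np.mean(np.abs(dataset.f) ** 2))
    noise = (rng.standard_normal(dataset.f.shape)
             + 1j * rng.standard_normal(dataset.f.shape)) / np.sqrt(2.0)
    return ScatterDataset(f=dataset.f + level * rms * noise,
                          geometry=dataset.geometry, noise_level=float(level))


def mie_cylinder_reference(radius, eps_cyl, geometry: AcquisitionGeometry,
                           tol=1e-12, n_max=400):
    """Series solution for TM line-source scattering by a centred cylinder.

    Returns the scattered field at the receivers for every transmitter,
    shape (T, R).  The cylindrical-harmonic series is truncated once the
    relative magnitude of the last term drops below ``tol`` for all
    receivers; failure to converge within ``n_max`` orders raises.
    """
    kb = geometry.k_background
    kc = wavenumber(geometry.frequency, eps_cyl)
    a = float(radius)

    def b_coeff(n):
        num = kc * jvp(n, kc * a) * jv(n, kb * a) - kb * jvp(n, kb * a) * jv(n, kc * a)
        den = kb * h2vp(n, kb * a) * jv(n, kc * a) - kc * jvp(n, kc * a) * hankel2(n, kb * a)
        return num / den

    out = np.zeros((geometry.n_tx, geometry.n_rx), dtype=complex)
    tx = geometry.tx_positions
    rx = geometry.rx_positions
    d = np.linalg.norm(tx, axis=1)            # (T,)
    phi_t = np.arctan2(tx[:, 1], tx[:, 0])
    rho = np.linalg.norm(rx, axis=1)          # (R,)
    phi_r = np.arctan2(rx[:, 1], rx[:, 0])
    dphi = phi_r[None, :] - phi_t[:, None]    # (T, R)

    total = np.zeros_like(out)
    for n in range(n_max + 1):
        An = -0.25j * hankel2(n, kb * d)      # (T,)
        term = (An * b_coeff(n))[:, None] * hankel2(n, kb * rho)[None, :]
        contrib = term * (np.cos(n * dphi) * (2.0 if n > 0 else 1.0))
        total += contrib
        scale = np.max(np.abs(total))
        if n > 5 and np.max(np.abs(term)) < tol * max(scale, 1e-300):
            return total
    raise RuntimeError("cylindrical-harmonic series did not converge")
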