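"""FEM-based Contrast Source Inversion with an inhomogeneous background.

The inverse problem is the minimisation of the normalized data-error plus
domain-error functional

    F_CSI(chi, w_t) = F_S(w_t) + F_D(chi, w_t)
    F_S  = sum_t ||f_t - M_S L[w_t]||^2 / sum_t ||f_t||^2
    F_D  = sum_t ||chi . E_t^inc - w_t + chi . M_D L[w_t]||^2
           / sum_t ||chi . E_t^inc||^2

over the contrast chi = (eps_r - eps_n)/eps_n on imaging-domain nodes and
the contrast sources w_t = chi . E_t (one per transmitter), where L is the
inverse of the FEM Helmholtz operator assembled with the numerical
background eps_n, M_S samples fields at the receivers and M_D restricts
them to the imaging domain.  Prior tissue information enters through
eps_n: wherever the prior equals the truth the contrast is zero.

The two variable sets are updated sequentially: one Polak-Ribiere
conjugate-gradient step with an exact (quadratic) line search per
transmitter for w_t, then the closed-form nodewise least-squares update
chi = sum_t w_t conj(E_t) / sum_t |E_t|^2 with the current total fields
E_t = E_t^inc + M_D L[w_t].  Contrast sources are initialized by
back-propagation.  The F_D normalizer is held at the previous contrast
during each w-subproblem so that subproblem stays exactly quadratic; a
candidate contrast update is accepted only if it does not increase the
recorded F_CSI, which makes the cost history non-increasing by
construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .forward import AcquisitionGeometry, FemSystem, ScatterDataset, build_mesh
from .mesh import Mesh


class ZeroContrastError(ValueError):
    """Raised when F_D is evaluated at an identically zero contrast."""


# ---------------------------------------------------------------------------
# operators


class FemOperatorBundle:
    """Field operators L, M_S, M_D built on a factorized FEM system.

    L maps contrast sources on imaging-domain (D) nodes to fields on the
    whole problem domain through the background FEM solve; because the
    system matrix is assembled with the prior background, tissue structure
    in the prior is baked into the forward map.
    """

    def __init__(self, mesh: Mesh, prior_eps_elem, geometry: AcquisitionGeometry,
                 prior_eps_nodes=None):
        self.mesh = mesh
        self.geometry = geometry
        self.fem = FemSystem(mesh, geometry, prior_eps_elem)
        d = geometry.domain_half_width
        self.d_idx = np.flatnonzero(
            np.all(np.abs(mesh.points) <= d, axis=1)
        )
        self.prior_eps_nodes = prior_eps_nodes
        self.P_D = self.fem.Mk2[:, self.d_idx].tocsc()
        self.Ms = mesh.interp_matrix(geometry.rx_positions).tocsr()
        self._MsH = self.Ms.conj().T.tocsc()
        self._PDH = self.P_D.conj().T.tocsc()

    @property
    def n_d(self):
        return self.d_idx.size

    @property
    def n_rx(self):
        return self.geometry.n_rx

    def L(self, W):
        """Fields on all mesh nodes radiated by contrast sources W (n_d, T)."""
        W = np.asarray(W, dtype=complex)
        return self.fem.solve(self.P_D @ W)

    def GS(self, W):
        return self.Ms @ self.L(W)

    def GD(self, W):
        return self.L(W)[self.d_idx]

    def apply_both(self, W):
        """(M_S L W, M_D L W) with a single factorized solve."""
        u = self.L(W)
        return self.Ms @ u, u[self.d_idx]

    def adjoint_mixed(self, rho, rd):
        """(M_S L)^H rho + (M_D L)^H rd with a single adjoint solve.

        Either argument may be None.  Inner products are conjugate-linear
        in the first slot, so the adjoint solve uses A^H.
        """
        rhs = 0.0
        if rho is not None:
            rhs = rhs + self._MsH @ np.asarray(rho, dtype=complex)
        if rd is not None:
            emb = np.zeros(
                (self.mesh.n_nodes,) + np.asarray(rd).shape[1:], dtype=complex
            )
            emb[self.d_idx] = rd
            rhs = rhs + emb
        return self._PDH @ self.fem.solve(rhs, adjoint=True)

    def incident_d(self):
        """Incident fields of all transmitters at D nodes, (n_d, T)."""
        return self.fem.incident_fields()[:, self.d_idx].T


class DenseOperatorBundle:
    """Explicit small matrices for L, M_S, M_D (test and toy problems)."""

    def __init__(self, L, Ms, Md):
        self.Lm = np.asarray(L, dtype=complex)
        self.Msm = np.asarray(Ms, dtype=complex)
        self.Mdm = np.asarray(Md, dtype=complex)
        self._GS = self.Msm @ self.Lm
        self._GD = self.Mdm @ self.Lm

    @property
    def n_d(self):
        return self.Lm.shape[1]

    @property
    def n_rx(self):
        return self.Msm.shape[0]

    def L(self, W):
        return self.Lm @ W

    def GS(self, W):
        return self._GS @ W

    def GD(self, W):
        return self._GD @ W

    def apply_both(self, W):
        return self.GS(W), self.GD(W)

    def adjoint_mixed(self, rho, rd):
        out = 0.0
        if rho is not None:
            out = out + self._GS.conj().T @ rho
        if rd is not None:
            out = out + self._GD.conj().T @ rd
        return out


def build_operators(mesh, prior, geometry, pixel_size=None) -> FemOperatorBundle:
    """Operator bundle for a prior background given as grids or nodal values."""
    if hasattr(prior, "eps_n"):
        px = pixel_size if pixel_size is not None else prior.region_labels.pixel_size
        eps_elem = mesh.sample_image(prior.eps_n, px, geometry.background_eps,
                                     at="elements")
        eps_nodes = mesh.sample_image(prior.eps_n, px, geometry.background_eps,
                                      at="nodes")
    else:
        eps = np.asarray(prior, dtype=complex)
        eps_elem = np.mean(eps[mesh.simplices], axis=1) if eps.shape[0] == mesh.n_nodes else eps
        eps_nodes = eps if eps.shape[0] == mesh.n_nodes else None
    return FemOperatorBundle(mesh, eps_elem, geometry, prior_eps_nodes=eps_nodes)


# ---------------------------------------------------------------------------
# state and cost


@dataclasses.dataclass
class CSIState:
    W: np.ndarray            # contrast sources, (n_d, T)
    chi: np.ndarray          # contrast, (n_d,)
    einc_d: np.ndarray       # incident fields at D nodes, (n_d, T)
    f: np.ndarray            # data, (R, T)
    GSW: np.ndarray          # cached M_S L W, (R, T)
    GDW: np.ndarray          # cached M_D L W, (n_d, T)
    eta_S: float
    eta_D: float             # 1 / sum_t ||chi . einc_t||^2 (previous chi)
    g_prev: np.ndarray | None = None
    v_prev: np.ndarray | None = None
    cost_history: list = dataclasses.field(default_factory=list)
    snapshots: dict = dataclasses.field(default_factory=dict)
    n_zero_field_nodes: int = 0

    def total_fields(self):
        return self.einc_d + self.GDW


def _fd_normalizer(chi, einc_d):
    return float(np.sum(np.abs(chi[:, None] * einc_d) ** 2))


def compute_cost(chi, W, dataset_f, ops, einc_d, GSW=None, GDW=None, eta_D=None):
    """(F_S, F_D, F_CSI) for the given contrast and contrast sources.

    ``eta_D`` may pin the domain normalizer to a previous contrast (the
    quadratic w-subproblem convention); by default it is recomputed from
    ``chi``.  An identically zero contrast makes F_D undefined and raises
    :class:`ZeroContrastError`.
    """
    f = np.asarray(dataset_f, dtype=complex)
    if GSW is None or GDW is None:
        GSW, GDW = ops.apply_both(W)
    rho = f - GSW
    F_S = float(np.sum(np.abs(rho) ** 2) / np.sum(np.abs(f) ** 2))
    r = chi[:, None] * (einc_d + GDW) - W
    if eta_D is None:
        denom = _fd_normalizer(chi, einc_d)
        if denom == 0.0:
            raise ZeroContrastError(
                "F_D is undefined for an identically zero contrast"
            )
        eta_D = 1.0 / denom
    F_D = float(np.sum(np.abs(r) ** 2) * eta_D)
    return F_S, F_D, F_S + F_D


# ---------------------------------------------------------------------------
# updates


def init_state(dataset, ops, einc_d=None) -> CSIState:
    """Back-propagation initialization of the contrast sources.

    w_t = s_t (M_S L)^H f_t with the per-transmitter real scalar s_t that
    minimizes the data error; the contrast follows from the analytic
    nodewise update.  Deterministic.
    """
    f = (dataset.f if isinstance(dataset, ScatterDataset) else np.asarray(dataset)).T
    if einc_d is None:
        einc_d = ops.incident_d()
    g = ops.adjoint_mixed(f, None)                    # (n_d, T)
    GSg = ops.GS(g)
    num = np.sum(np.abs(g) ** 2, axis=0)
    den = np.sum(np.abs(GSg) ** 2, axis=0)
    s = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    W = g * s[None, :]
    GSW, GDW = ops.apply_both(W)
    E = einc_d + GDW
    chi, n_zero = _chi_update(W, E)
    f_norm = float(np.sum(np.abs(f) ** 2))
    eta_S = 1.0 / f_norm if f_norm > 0 else 1.0
    denom = _fd_normalizer(chi, einc_d)
    eta_D = 1.0 / denom if denom > 0 else np.inf
    return CSIState(W=W, chi=chi, einc_d=einc_d, f=f, GSW=GSW, GDW=GDW,
                    eta_S=eta_S, eta_D=eta_D, n_zero_field_nodes=n_zero)


def _chi_update(W, E):
    """Closed-form nodewise least-squares contrast given total fields."""
    num = np.sum(W * np.conj(E), axis=1)
    den = np.sum(np.abs(E) ** 2, axis=1)
    zero = den == 0.0
    chi = np.zeros_like(num)
    np.divide(num, den, out=chi, where=~zero)
    return chi, int(zero.sum())


def update_sources(state: CSIState, ops) -> CSIState:
    """One Polak-Ribiere CG step on all w_t with chi (and eta_D) fixed.

    The exact line search minimizes the per-transmitter quadratic in the
    step length, so F_CSI cannot increase.
    """
    chi = state.chi
    rho = state.f - state.GSW
    r = chi[:, None] * state.total_fields() - state.W
    # conjugate cogradient of F wrt w_t
    g = ops.adjoint_mixed(-state.eta_S * rho, state.eta_D * np.conj(chi)[:, None] * r)
    g = g - state.eta_D * r
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite CSI gradient")

    if state.g_prev is None:
        v = -g
    else:
        num = np.real(np.sum(np.conj(g) * (g - state.g_prev), axis=0))
        den = np.sum(np.abs(state.g_prev) ** 2, axis=0)
        beta = np.where(den > 0, np.maximum(num / np.where(den > 0, den, 1.0), 0.0), 0.0)
        v = -g + beta[None, :] * state.v_prev

    a, GDv = ops.apply_both(v)                       # (R, T), (n_d, T)
    b = chi[:, None] * GDv - v
    num = (state.eta_S * np.real(np.sum(np.conj(a) * rho, axis=0))
           - state.eta_D * np.real(np.sum(np.conj(b) * r, axis=0)))
    den = (state.eta_S * np.sum(np.abs(a) ** 2, axis=0)
           + state.eta_D * np.sum(np.abs(b) ** 2, axis=0))
    alpha = np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    state.W = state.W + alpha[None, :] * v
    state.GSW = state.GSW + alpha[None, :] * a
    state.GDW = state.GDW + alpha[None, :] * GDv
    state.g_prev = g
    state.v_prev = v
    return state


def update_contrast(state: CSIState, ops=None) -> CSIState:
    """Closed-form contrast update from the current total fields."""
    chi, n_zero = _chi_update(state.W, state.total_fields())
    state.chi = chi
    state.n_zero_field_nodes = n_zero
    return state


def total_permittivity(chi, eps_n):
    """Invert the contrast definition: eps_r = eps_n (1 + chi)."""
    return np.asarray(eps_n) * (1.0 + np.asarray(chi))


def contrast_of(eps_r, eps_n):
    """chi = (eps_r - eps_n) / eps_n."""
    eps_n = np.asarray(eps_n)
    return (np.asarray(eps_r) - eps_n) / eps_n


def rasterize(node_values, mesh: Mesh, grid_shape, pixel_size, fill=0.0):
    """Barycentric interpolation of nodal values onto pixel centres.

    Pixels outside the mesh take ``fill``.
    """
    m, n = grid_shape
    y = (np.arange(m) + 0.5) * pixel_size - m * pixel_size / 2.0
    x = (np.arange(n) + 0.5) * pixel_size - n * pixel_size / 2.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    R = mesh.interp_matrix(pts)
    vals = R @ np.asarray(node_values, dtype=complex)
    outside = np.asarray(R.sum(axis=1)).ravel() < 0.5
    vals[outside] = fill
    return vals.reshape(m, n)


# ---------------------------------------------------------------------------
# model / results


def run_csi(dataset, prior, n_iters=250, snapshot_iters=(), geometry=None,
            mesh=None, tol=1e-10, max_edge_frac=0.1, eps_max=None):
    """Functional entry point; see :class:`ContrastSourceInversion`."""
    model = ContrastSourceInversion(dataset, prior, geometry=geometry, mesh=mesh,
                                    max_edge_frac=max_edge_frac, eps_max=eps_max)
    return model.fit(n_iters=n_iters, snapshot_iters=snapshot_iters, tol=tol)


class ContrastSourceInversion:
    """Contrast Source Inversion model for one scattered-field dataset.

    Parameters
    ----------
    dataset : ScatterDataset
        Measured scattered fields referenced to the prior background.
    prior : PriorBackground
        Tumor-free numerical background embedding the tissue prior.
    geometry : AcquisitionGeometry, optional
        Defaults to the dataset's geometry.
    mesh : Mesh, optional
        Inversion mesh; built at ``max_edge_frac`` of the shortest
        expected wavelength when omitted.
    """

    def __init__(self, dataset: ScatterDataset, prior, geometry=None, mesh=None,
                 max_edge_frac=0.1, eps_max=None):
        self.dataset = dataset
        self.prior = prior
        self.geometry = dataset.geometry if geometry is None else geometry
        if eps_max is None:
            eps_max = 1.5 * float(np.max(prior.eps_n_real))
        if mesh is None:
            mesh = build_mesh(self.geometry, eps_max, max_edge_frac)
        self.mesh = mesh
        self.pixel_size = prior.region_labels.pixel_size
        self.grid_shape = prior.eps_n_real.shape
        self.ops = build_operators(mesh, prior, self.geometry,
                                   pixel_size=self.pixel_size)

    def fit(self, n_iters=250, snapshot_iters=(), tol=1e-10) -> "CSIResults":
        if n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        snapshot_iters = sorted(set(int(i) for i in snapshot_iters))
        if snapshot_iters and not (1 <= snapshot_iters[0]
                                   and snapshot_iters[-1] <= n_iters):
            raise ValueError("snapshot_iters must lie within [1, n_iters]")
        ops = self.ops
        state = init_state(self.dataset, ops)
        prev_cost = None
        for it in range(1, n_iters + 1):
            state = update_sources(state, ops)
            # cost after the w step, at the normalizer used by that step
            fs, fd, fc = compute_cost(state.chi, state.W, state.f, ops,
                                      state.einc_d, state.GSW, state.GDW,
                                      eta_D=state.eta_D)
            # guarded contrast update: accept only if the recorded cost
            # does not increase once the normalizer moves with chi
            chi_old, eta_old, nz_old = state.chi, state.eta_D, state.n_zero_field_nodes
            state = update_contrast(state)
            denom = _fd_normalizer(state.chi, state.einc_d)
            if denom > 0:
                fs2, fd2, fc2 = compute_cost(state.chi, state.W, state.f, ops,
                                             state.einc_d, state.GSW, state.GDW,
                                             eta_D=1.0 / denom)
                if fc2 <= fc * (1.0 + 1e-12) + 1e-300:
                    state.eta_D = 1.0 / denom
                    fs, fd, fc = fs2, fd2, fc2
                else:
                    state.chi, state.eta_D = chi_old, eta_old
                    state.n_zero_field_nodes = nz_old
            else:
                state.chi, state.eta_D = chi_old, eta_old
                state.n_zero_field_nodes = nz_old
            if prev_cost is not None and fc > prev_cost * (1.0 + tol):
                raise RuntimeError(
                    f"F_CSI increased at iteration {it}: {prev_cost} -> {fc}; "
                    f"history: {[h[3] for h in state.cost_history]}"
                )
            prev_cost = fc
            state.cost_history.append((it, fs, fd, fc))
            if it in snapshot_iters:
                state.snapshots[it] = state.chi.copy()
        return CSIResults(model=self, state=state)


class CSIResults:
    """Reconstruction result: contrast, snapshots and cost history."""

    def __init__(self, model: ContrastSourceInversion, state: CSIState):
        self.model = model
        self.state = state
        self.chi = state.chi
        self.snapshots = state.snapshots

    @property
    def cost_history(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.state.cost_history, columns=["iteration", "F_S", "F_D", "F_CSI"]
        )

    def _embed(self, chi):
        full = np.zeros(self.model.mesh.n_nodes, dtype=complex)
        full[self.model.ops.d_idx] = chi
        return full

    def chi_image(self, iteration=None):
        """Contrast rasterized onto the prior pixel grid (complex)."""
        chi = self.chi if iteration is None else self.snapshots[iteration]
        return rasterize(self._embed(chi), self.model.mesh,
                         self.model.grid_shape, self.model.pixel_size, fill=0.0)

    def eps_image(self, iteration=None):
        """Reconstructed complex permittivity eps_n (1 + chi) on the grid."""
        chi_img = self.chi_image(iteration)
        eps_n = self.model.prior.eps_n
        return eps_n * (1.0 + chi_img)

    def summary(self):
        h = self.cost_history
        lines = [
            "Contrast Source Inversion results",
            f"  transmitters/receivers : {self.model.geometry.n_tx}/{self.model.geometry.n_rx}",
            f"  mesh nodes / D nodes   : {self.model.mesh.n_nodes} / {self.model.ops.n_d}",
            f"  iterations             : {len(h)}",
            f"  final F_S              : {h['F_S'].iloc[-1]:.6g}",
            f"  final F_D              : {h['F_D'].iloc[-1]:.6g}",
            f"  final F_CSI            : {h['F_CSI'].iloc[-1]:.6g}",
            f"  max |chi|              : {np.abs(self.chi).max():.4g}",
        ]
        return "\n".join(lines)
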