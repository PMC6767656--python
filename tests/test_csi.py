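"""Contrast Source Inversion: operators, cost, updates, reconstruction."""

import json

import numpy as np
import pytest

from csinet.csi import (ContrastSourceInversion, DenseOperatorBundle,
                        ZeroContrastError, build_operators, compute_cost,
                        contrast_of, init_state, rasterize, total_permittivity,
                        update_contrast, update_sources)
from csinet.forward import ScatterDataset, build_mesh
from csinet.mesh import build_disk_mesh

from conftest import homogeneous_prior


def load_toy(fixtures_dir):
    d = json.loads((fixtures_dir / "toy_csi.json").read_text())

    def l2c(v):
        return np.asarray(v[0]) + 1j * np.asarray(v[1])

    return {k: l2c(v) for k, v in d.items()}


@pytest.fixture(scope="module")
def toy(fixtures_dir):
    return load_toy(fixtures_dir)


@pytest.fixture(scope="module")
def toy_ops(toy):
    return DenseOperatorBundle(toy["L"], toy["Ms"], toy["Md"])


@pytest.fixture(scope="module")
def fem_ops(desk_geometry):
    mesh = build_mesh(desk_geometry, 50.0, 0.1)
    prior = homogeneous_prior((64, 64), 0.2, desk_geometry.background_eps)
    return build_operators(mesh, prior, desk_geometry)


class TestOperators:
    def test_zero_source_zero_field(self, fem_ops):
        W = np.zeros((fem_ops.n_d, 3), dtype=complex)
        assert np.abs(fem_ops.L(W)).max() == 0.0

    def test_linearity(self, fem_ops):
        rng = np.random.default_rng(0)
        w1 = rng.standard_normal((fem_ops.n_d, 2)) + 1j * rng.standard_normal((fem_ops.n_d, 2))
        w2 = rng.standard_normal((fem_ops.n_d, 2)) + 1j * rng.standard_normal((fem_ops.n_d, 2))
        a, b = 1.7 - 0.3j, -0.4 + 2.1j
        lhs = fem_ops.GS(a * w1 + b * w2)
        rhs = a * fem_ops.GS(w1) + b * fem_ops.GS(w2)
        assert np.abs(lhs - rhs).max() <= 1e-10 * np.abs(rhs).max()

    def test_adjoint_identity(self, fem_ops):
        """<G w, f> == <w, G^H f> (conjugate-linear first argument)."""
        rng = np.random.default_rng(1)
        w = rng.standard_normal((fem_ops.n_d, 1)) + 1j * rng.standard_normal((fem_ops.n_d, 1))
        f = rng.standard_normal((fem_ops.n_rx, 1)) + 1j * rng.standard_normal((fem_ops.n_rx, 1))
        lhs = np.vdot(f, fem_ops.GS(w))
        rhs = np.vdot(fem_ops.adjoint_mixed(f, None), w)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)
        rd = rng.standard_normal((fem_ops.n_d, 1)) + 1j * rng.standard_normal((fem_ops.n_d, 1))
        lhs = np.vdot(rd, fem_ops.GD(w))
        rhs = np.vdot(fem_ops.adjoint_mixed(None, rd), w)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_point_source_response_decays(self, fem_ops):
        """M_D L of a point-like source decays away from the source."""
        W = np.zeros((fem_ops.n_d, 1), dtype=complex)
        W[0] = 1.0
        u = np.abs(fem_ops.GD(W)[:, 0])
        pts = fem_ops.mesh.points[fem_ops.d_idx]
        d = np.linalg.norm(pts - pts[0], axis=1)
        near = u[(d > 0.5) & (d < 1.5)].mean()
        far = u[d > 6.0].mean()
        assert far < near


class TestCost:
    def test_consistent_pair_has_zero_cost(self, toy, toy_ops):
        fs, fd, fc = compute_cost(toy["chi"], toy["W"], toy["f"], toy_ops, toy["einc"])
        assert fc <= 1e-10

    def test_zero_sources_unit_data_error(self, toy, toy_ops):
        W0 = np.zeros_like(toy["W"])
        fs, fd, fc = compute_cost(toy["chi"], W0, toy["f"], toy_ops, toy["einc"])
        assert fs == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_arithmetic(self, toy, toy_ops):
        """Direct evaluation of the normalized two-term functional."""
        rng = np.random.default_rng(3)
        chi = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        W = rng.standard_normal((3, 2)) + 1j * rng.standard_normal((3, 2))
        fs, fd, fc = compute_cost(chi, W, toy["f"], toy_ops, toy["einc"])
        GS = toy["Ms"] @ toy["L"]
        GD = toy["Md"] @ toy["L"]
        fs_ref = fd_ref = 0.0
        for t in range(2):
            rho = toy["f"][:, t] - GS @ W[:, t]
            fs_ref += np.sum(np.abs(rho) ** 2)
            E = toy["einc"][:, t] + GD @ W[:, t]
            fd_ref += np.sum(np.abs(chi * E - W[:, t]) ** 2)
        fs_ref /= np.sum(np.abs(toy["f"]) ** 2)
        fd_ref /= sum(np.sum(np.abs(chi * toy["einc"][:, t]) ** 2) for t in range(2))
        assert fs == pytest.approx(fs_ref, rel=1e-12)
        assert fd == pytest.approx(fd_ref, rel=1e-12)

    def test_zero_contrast_signalled(self, toy, toy_ops):
        with pytest.raises(ZeroContrastError):
            compute_cost(np.zeros(3, dtype=complex), toy["W"], toy["f"],
                         toy_ops, toy["einc"])


class TestInit:
    def test_zero_data_zero_sources(self, toy_ops, toy):
        state = init_state(np.zeros((2, 2), dtype=complex) + 0j, toy_ops,
                           einc_d=toy["einc"])
        assert np.abs(state.W).max() == 0.0

    def test_initial_data_error_bounded(self, toy, toy_ops):
        state = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        fs, _, _ = compute_cost(state.chi, state.W, state.f, toy_ops,
                                toy["einc"], eta_D=state.eta_D)
        assert fs <= 1.0 + 1e-12

    def test_deterministic(self, toy, toy_ops):
        a = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        b = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.chi, b.chi)


class TestUpdates:
    @pytest.fixture()
    def noisy_state(self, toy, toy_ops):
        rng = np.random.default_rng(7)
        f = toy["f"] + 0.1 * (rng.standard_normal(toy["f"].shape)
                              + 1j * rng.standard_normal(toy["f"].shape))
        return init_state(f.T, toy_ops, einc_d=toy["einc"])

    def test_source_step_never_increases_cost(self, noisy_state, toy_ops):
        state = noisy_state
        prev = None
        for _ in range(50):
            state = update_sources(state, toy_ops)
            fs, fd, fc = compute_cost(state.chi, state.W, state.f, toy_ops,
                                      state.einc_d, state.GSW, state.GDW,
                                      eta_D=state.eta_D)
            if prev is not None:
                assert fc <= prev * (1 + 1e-10)
            prev = fc

    def test_stationary_at_consistent_solution(self, toy, toy_ops):
        state = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        state.W = toy["W"].copy()
        state.chi = toy["chi"].copy()
        state.GSW, state.GDW = toy_ops.apply_both(state.W)
        denom = np.sum(np.abs(state.chi[:, None] * state.einc_d) ** 2)
        state.eta_D = 1.0 / denom
        W_before = state.W.copy()
        state = update_sources(state, toy_ops)
        assert np.abs(state.W - W_before).max() < 1e-8 * np.abs(W_before).max()

    def test_contrast_closed_form_exact_ratio(self, toy, toy_ops):
        state = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        c = 0.37 - 0.21j
        E = state.total_fields()
        state.W = c * E
        state = update_contrast(state)
        np.testing.assert_allclose(state.chi, np.full(3, c), rtol=1e-12)

    def test_contrast_single_transmitter(self, toy, toy_ops):
        state = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        state.W = state.W[:, :1]
        state.GDW = state.GDW[:, :1]
        state.einc_d = state.einc_d[:, :1]
        E = state.total_fields()
        state = update_contrast(state)
        np.testing.assert_allclose(state.chi, (state.W[:, 0] / E[:, 0]), rtol=1e-12)

    def test_contrast_matches_per_node_least_squares(self, toy, toy_ops):
        rng = np.random.default_rng(5)
        state = init_state(toy["f"].T, toy_ops, einc_d=toy["einc"])
        state.W = rng.standard_normal((3, 2)) + 1j * rng.standard_normal((3, 2))
        state.GDW = toy_ops.GD(state.W)
        E = state.total_fields()
        state = update_contrast(state)
        for node in range(3):
            chi_ref = np.linalg.lstsq(E[node][:, None], state.W[node], rcond=None)[0][0]
            assert state.chi[node] == pytest.approx(chi_ref, rel=1e-10)


class TestAlgebra:
    def test_total_permittivity_identity_and_arithmetic(self):
        eps_n = np.array([23.0 - 1.0j, 10.0])
        assert (total_permittivity(np.zeros(2), eps_n) == eps_n).all()
        assert total_permittivity(np.array([1.0, 0.0]), np.array([23.0, 5.0]))[0] == 46.0

    def test_contrast_round_trip(self):
        rng = np.random.default_rng(2)
        eps_n = 20 + 5 * rng.random(10) - 1j * rng.random(10)
        chi = rng.standard_normal(10) + 1j * 0.1 * rng.standard_normal(10)
        back = contrast_of(total_permittivity(chi, eps_n), eps_n)
        np.testing.assert_allclose(back, chi, atol=1e-12)


class TestRasterize:
    @pytest.fixture(scope="class")
    def mesh(self):
        return build_disk_mesh(8.0, 0.6)

    def test_constant_field(self, mesh):
        vals = np.full(mesh.n_nodes, 2.5 + 0.5j)
        img = rasterize(vals, mesh, (16, 16), 0.4)
        np.testing.assert_allclose(img, 2.5 + 0.5j, rtol=1e-12)

    def test_linear_function_exact(self, mesh):
        """P1 interpolation reproduces affine nodal fields exactly."""
        a, b, c = 0.3, -1.2, 4.0
        vals = a * mesh.points[:, 0] + b * mesh.points[:, 1] + c
        img = rasterize(vals.astype(complex), mesh, (16, 16), 0.4)
        y = (np.arange(16) + 0.5) * 0.4 - 3.2
        yy, xx = np.meshgrid(y, y, indexing="ij")
        np.testing.assert_allclose(img.real, a * xx + b * yy + c, atol=1e-10)


class TestReconstruction:
    def test_snapshot_costs_monotone(self, desk_geometry, fixtures_dir):
        """Later-iteration snapshots always carry lower cost."""
        from csinet.forward import mie_cylinder_reference

        geo = desk_geometry
        f = mie_cylinder_reference(3.0, geo.background_eps * 1.15, geo)
        ds = ScatterDataset(f=f, geometry=geo)
        prior = homogeneous_prior((64, 64), 0.2, geo.background_eps)
        res = ContrastSourceInversion(ds, prior).fit(
            n_iters=30, snapshot_iters=(5, 15, 30))
        h = res.cost_history.set_index("iteration")["F_CSI"]
        assert h.loc[30] <= h.loc[15] <= h.loc[5]
        assert sorted(res.snapshots) == [5, 15, 30]

    def test_invalid_snapshot_iters_rejected(self, desk_geometry):
        ds = ScatterDataset(f=np.ones((24, 24), dtype=complex),
                            geometry=desk_geometry)
        prior = homogeneous_prior((64, 64), 0.2, desk_geometry.background_eps)
        model = ContrastSourceInversion(ds, prior)
        with pytest.raises(ValueError):
            model.fit(n_iters=10, snapshot_iters=(20,))
        with pytest.raises(ValueError):
            model.fit(n_iters=0)
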