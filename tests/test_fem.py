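"""Coupled FEM solver: assembly, linear solves, splitting, conservation."""

import numpy as np
import pytest
import scipy.sparse as sp

import cardioem as cm
from cardioem import hex8
from cardioem.errors import (BlowUpError, InvertedElementError,
                             WellPosednessError)
from cardioem.fem import CoupledSystem, solve_linear
from cardioem.ionic import STATE_NAMES, CellState


def strip_mesh(n_elems=10, h=0.01):
    """1D cable: n_elems x 1 x 1 hexes along x."""
    spec = cm.GeometrySpec(kind="slab",
                           dimensions=(n_elems * h, h, 0.001),
                           mesh_size=h, pinned="none",
                           fiber_vector=(1.0, 0.0, 0.0))
    return cm.make_slab(spec)


class TestSolveLinear:
    def test_identity_returns_rhs(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=40)
        system = CoupledSystem(matrix=sp.identity(40, format="csr"), rhs=b)
        for solver in ("direct", "gmres_jacobi"):
            x = solve_linear(system, cm.SolverConfig(linear_solver=solver))
            assert np.allclose(x, b, atol=1e-10)

    def test_random_spd_matches_direct(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(100, 100))
        A = sp.csr_matrix(A @ A.T + 100 * np.eye(100))
        b = rng.normal(size=100)
        xg = solve_linear(CoupledSystem(A, b),
                          cm.SolverConfig(linear_solver="gmres_jacobi"))
        xd = solve_linear(CoupledSystem(A, b),
                          cm.SolverConfig(linear_solver="direct"))
        assert np.linalg.norm(xg - xd) / np.linalg.norm(xd) < 1e-7

    def test_zero_diagonal_raises_well_posedness(self):
        A = sp.csr_matrix(np.diag([1.0, 0.0, 1.0]))
        with pytest.raises(WellPosednessError):
            solve_linear(CoupledSystem(A, np.ones(3)), cm.SolverConfig())

    def test_unpinned_mechanics_raises(self):
        mesh = strip_mesh()  # pinned="none"
        stepper = cm.CoupledStepper(mesh, mode="coupled")
        with pytest.raises(WellPosednessError, match="fixed"):
            stepper.assemble_coupled()


class TestAssembly:
    def test_rest_state_is_equilibrium(self, small_slab):
        mesh, _ = small_slab
        stepper = cm.CoupledStepper(mesh, mode="coupled")
        stepper.v_star = stepper.cells.v.copy()
        system = stepper.assemble_coupled()
        assert np.linalg.norm(system.rhs) < 1e-12

    def test_single_element_force_matches_constitutive_law(
            self, single_element_mesh):
        """A homogeneously deformed element's internal force must equal the
        closed-form Kirchhoff stress mapped through the current shape-function
        gradients (independent quadrature in the test)."""
        mesh = single_element_mesh
        F = np.array([[1.1, 0.05, 0.0],
                      [0.0, 0.95, 0.02],
                      [0.0, 0.0, 1.03]])
        mesh.x_cur = mesh.X_ref @ F.T
        stepper = cm.CoupledStepper(mesh, mode="ep_only")
        stepper.t_a[:] = 0.02
        xe = mesh.x_cur[mesh.hexes]
        ta_gp = stepper._ta_gp()
        f, _ = stepper._mech_force(xe, ta_gp)

        kin = cm.compute_kinematics(F, mesh.a0_field[0])
        sig = cm.passive_stress(kin, cm.MaterialParams()) \
            + cm.active_stress(0.02, kin.kappa)
        # independent quadrature over the current configuration
        f_ref = np.zeros((8, 3))
        Xe = mesh.X_ref[mesh.hexes[0]]
        for g, xi in enumerate(hex8.GAUSS_XI):
            dN = hex8.shape_gradients(xi)
            Jref = Xe.T @ dN
            dNdX = dN @ np.linalg.inv(Jref).T
            dNdx = dNdX @ np.linalg.inv(F)
            w = np.linalg.det(Jref) * np.linalg.det(F)
            f_ref += w * dNdx @ sig
        assert np.allclose(f[0], f_ref, rtol=1e-10, atol=1e-14)

    def test_stress_at_gauss_points_matches_continuum_module(
            self, single_element_mesh):
        mesh = single_element_mesh
        F = np.diag([1.15, 0.9, 1.0])
        mesh.x_cur = mesh.X_ref @ F.T
        stepper = cm.CoupledStepper(mesh, mode="ep_only")
        _, _, _, _, kappa, B = stepper._geometry_at(mesh.x_cur[mesh.hexes])
        kin = cm.compute_kinematics(F, mesh.a0_field[0])
        assert np.allclose(kappa, kin.kappa, atol=1e-13)
        assert np.allclose(B, kin.B, atol=1e-13)

    def test_inverted_mesh_rejected(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, -1], [1, 0, -1], [1, 1, -1], [0, 1, -1]],
                     dtype=float)
        mesh = cm.Mesh(X_ref=X, hexes=[[0, 1, 2, 3, 4, 5, 6, 7]],
                       a0_field=[[1.0, 0, 0]])
        with pytest.raises(InvertedElementError):
            mesh.check()


class TestReactionStage:
    def test_matches_standalone_cell_integrator(self, single_element_mesh):
        """Splitting consistency: 20 substeps of the tissue reaction stage on
        a uniform element reproduce the standalone cell integration."""
        mesh = single_element_mesh
        stepper = cm.CoupledStepper(mesh, mode="ep_only",
                                    stim_nodes=np.arange(8))
        stepper.reaction_substeps(0.0)

        params, tension = cm.IonicParams(), cm.ActiveTensionParams()
        s = cm.resting_state()
        ta = 0.0
        for i in range(20):
            t = i * 0.005
            stim = cm.stimulus_waveform(t, 0.0, params)
            v_old = s.v
            s = cm.step_cell(s, params, stim=stim, dt=0.005)
            ta = cm.step_tension(ta, v_old, 0.005, tension)
        assert np.allclose(stepper.cells.v, float(s.v), atol=1e-12)
        assert np.allclose(stepper.t_a, float(ta), atol=1e-15)

    def test_rest_is_fixed_point_without_stimulus(self, small_slab):
        mesh, _ = small_slab
        stepper = cm.CoupledStepper(mesh, mode="ep_only")
        v0 = stepper.cells.v.copy()
        for k in range(10):
            stepper.reaction_substeps(k * 0.1)
        assert np.abs(stepper.cells.v - v0).max() < 1e-3

    def test_scar_nodes_held_at_rest(self):
        mesh = strip_mesh(n_elems=3, h=0.04)
        mesh.scar_elements = np.array([0])
        mesh.fixed_nodes = np.array([0])
        stim = np.flatnonzero(mesh.X_ref[:, 0] > 0.05)
        stepper = cm.CoupledStepper(mesh, mode="ep_only", stim_nodes=stim,
                                    solver=cm.SolverConfig(linear_solver="direct"))
        scar_nodes = np.flatnonzero(mesh.scar_node_mask())
        assert scar_nodes.size > 0
        v_rest = stepper.cells.v[scar_nodes].copy()
        for k in range(50):
            stepper.step(k * 0.1)
        assert stepper.cells.v[stim].max() > 0.0
        assert np.allclose(stepper.cells.v[scar_nodes], v_rest, atol=1e-9)

    def test_blowup_reports_node_and_time(self, small_slab):
        mesh, spec = small_slab
        stim = cm.select_stimulus_nodes(
            mesh, cm.StimulusSpec(kind="ball", center=(0, 0, 0.0005),
                                  radius=0.05))
        stepper = cm.CoupledStepper(
            mesh, ionic=cm.IonicParams(stim_amplitude=1e6),
            mode="ep_only", stim_nodes=stim)
        with pytest.raises(BlowUpError, match="node"):
            for k in range(20):
                stepper.step(k * 0.1)


class TestDiffusion:
    def test_neumann_mass_conservation(self, small_slab):
        """Pure no-flux diffusion with implicit Euler conserves the
        mass-matrix-weighted mean of v to 1e-10 per step."""
        mesh, _ = small_slab
        stepper = cm.CoupledStepper(
            mesh, mode="ep_only",
            solver=cm.SolverConfig(linear_solver="direct"))
        rng = np.random.default_rng(4)
        stepper.cells.v = rng.uniform(-90.0, 20.0, mesh.n_nodes)
        M = stepper.mass_matrix()
        one = np.ones(mesh.n_nodes)
        m0 = one @ (M @ stepper.cells.v)
        for k in range(20):
            stepper.step(k * 0.1, skip_reaction=True)
            mk = one @ (M @ stepper.cells.v)
            assert abs(mk - m0) / abs(m0) < 1e-10

    def test_cosine_eigenmode_decay(self):
        """Diffusion block vs the analytic heat-equation eigenmode: the
        lowest cosine mode on an insulated slab decays as exp(-D pi^2/L^2 t)."""
        L = 0.4
        spec = cm.GeometrySpec(kind="slab", dimensions=(L, L, 0.001),
                               mesh_size=0.02, pinned="none")
        mesh = cm.make_slab(spec)
        stepper = cm.CoupledStepper(
            mesh, mode="ep_only", material=cm.MaterialParams(d_ani=0.0),
            solver=cm.SolverConfig(linear_solver="direct"))
        amp = 10.0
        stepper.cells.v = amp * np.cos(np.pi * (mesh.X_ref[:, 0] + L / 2) / L)
        lam = 0.001 * np.pi ** 2 / L ** 2
        t_end, dt = 5.0, 0.1
        for k in range(int(t_end / dt)):
            stepper.step(k * dt, skip_reaction=True)
        expected = amp * np.exp(-lam * t_end)
        assert stepper.cells.v.max() == pytest.approx(expected, rel=0.02)


class TestCoupledStepping:
    def test_splitting_error_halves_with_dt(self):
        """First-order operator splitting on a 10-element cable: halving both
        dt_ode and dt_pde roughly halves the error against a fine-dt
        reference."""
        t_end = 10.0

        def run(dt_pde, dt_ode):
            mesh = strip_mesh(n_elems=10, h=0.01)
            mesh.fixed_nodes = np.array([0])
            stim = np.flatnonzero(mesh.X_ref[:, 0] < -0.045)
            stepper = cm.CoupledStepper(
                mesh, mode="ep_only", stim_nodes=stim,
                material=cm.MaterialParams(d_ani=0.0),
                solver=cm.SolverConfig(dt_pde=dt_pde, dt_ode=dt_ode,
                                       linear_solver="direct"))
            for k in range(int(round(t_end / dt_pde))):
                stepper.step(k * dt_pde)
            return stepper.cells.v.copy()

        v_ref = run(0.005, 0.005)
        e1 = np.abs(run(0.1, 0.005) - v_ref).max()
        e2 = np.abs(run(0.05, 0.0025) - v_ref).max()
        assert e1 / e2 == pytest.approx(2.0, rel=0.5)

    def test_more_newton_iterations_agree_with_single_pass(self):
        """One linearized solve per step vs converged Newton: nodal voltage
        differs by < 0.5 mV over a short coupled run on a small tissue."""
        def run(newton_iters):
            spec = cm.GeometrySpec(
                kind="slab", dimensions=(0.08, 0.08, 0.001), mesh_size=0.01,
                stimulus=cm.StimulusSpec(kind="box", center=(0, 0, 0.0005),
                                         radius=0.02))
            mesh = cm.make_slab(spec)
            stim = cm.select_stimulus_nodes(mesh, spec.stimulus)
            stepper = cm.CoupledStepper(
                mesh, mode="coupled", stim_nodes=stim,
                solver=cm.SolverConfig(newton_iters=newton_iters,
                                       linear_solver="direct"))
            for k in range(100):
                stepper.step(k * 0.1)
            return stepper.cells.v.copy()

        assert np.abs(run(1) - run(5)).max() < 0.5

    def test_gmres_and_direct_agree_on_coupled_step(self):
        def run(solver):
            spec = cm.GeometrySpec(
                kind="slab", dimensions=(0.08, 0.08, 0.001), mesh_size=0.02,
                stimulus=cm.StimulusSpec(kind="box", center=(0, 0, 0.0005),
                                         radius=0.02))
            mesh = cm.make_slab(spec)
            stim = cm.select_stimulus_nodes(mesh, spec.stimulus)
            stepper = cm.CoupledStepper(
                mesh, mode="coupled", stim_nodes=stim,
                solver=cm.SolverConfig(linear_solver=solver))
            for k in range(20):
                stepper.step(k * 0.1)
            return stepper.cells.v.copy()

        assert np.abs(run("direct") - run("gmres_jacobi")).max() < 1e-4
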