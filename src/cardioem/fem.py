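"""Coupled finite-element solver: operator splitting, assembly, monolithic 4N solve.

Each PDE time step of length ``dt_pde`` (default 0.1 ms) consists of

1. a *reaction* stage: ``dt_pde/dt_ode`` forward-Euler substeps of the local
   cell ODEs (Beeler-Reuter ionic model with stimulus and stretch-activated
   current, plus the active-tension ODE) at every non-scar node; then
2. a *PDE* stage: one or more linearized solves of the coupled system

       G_v = int_Omega [ dv/dt * w + grad(w) . D grad(v) ] dv = 0   (implicit Euler)
       G_x = int_Omega grad(dx) : (sigma_pass + sigma_act) dv
             - int_Omega dx . b dv = 0                              (quasi-static)

   discretized with trilinear hexahedra and 2x2x2 Gauss quadrature in an
   updated-Lagrangian setting: integrals and spatial gradients are taken over
   the current configuration, while the deformation gradient F is the total
   one accumulated from the original configuration.  The per-node unknowns
   (dx, dy, dz, dv) are gathered into one sparse 4N x 4N system, solved by
   Jacobi-preconditioned GMRES (or a direct sparse LU as the documented
   fallback), and applied as increments.

The mechanics tangent is assembled by per-element finite differences of the
internal-force residual; the voltage block (consistent mass / dt + stiffness)
is analytic.  The cross-sensitivity blocks are lagged within the step: the
active tension is frozen during the PDE stage (it advances in the reaction
stage) and the geometry dependence of the diffusion operator is evaluated at
the current iterate, so with ``newton_iters = 1`` the scheme is the classic
single-linearization (semi-implicit) update.

Boundary conditions: no-flux and traction-free surfaces contribute nothing to
the weak forms; pinned nodes (the essential boundary) have their three
displacement rows replaced by identity with zero right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import hex8
from .active_tension import ActiveTensionParams, step_tension
from .continuum import MaterialParams, compute_kinematics
from .errors import (BlowUpError, LinearSolverError, WellPosednessError)
from .ionic import (CellState, IonicParams, STATE_NAMES, ionic_currents,
                    resting_state, step_cell, stimulus_waveform)
from .mesh import Mesh


@dataclass
class SolverConfig:
    """Time stepping and linear-solver settings."""

    dt_ode: float = 0.005          # reaction substep, ms
    dt_pde: float = 0.1            # PDE step, ms (integer multiple of dt_ode)
    newton_iters: int = 1          # linearized solves per PDE step
    linear_solver: str = "gmres_jacobi"  # "gmres_jacobi" | "direct"
    gmres_tol: float = 1e-8
    gmres_restart: int = 200
    gmres_maxiter: int = 50        # outer (restart) cycles
    body_force: Sequence[float] = (0.0, 0.0, 0.0)  # MPa/cm

    def n_substeps(self) -> int:
        return int(round(self.dt_pde / self.dt_ode))

    def validate(self):
        errs = []
        if not self.dt_ode > 0 or not self.dt_pde > 0:
            errs.append("solver.dt_ode and dt_pde must be > 0")
        else:
            ratio = self.dt_pde / self.dt_ode
            if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                errs.append(
                    f"solver.dt_pde ({self.dt_pde}) must be an integer multiple "
                    f"of dt_ode ({self.dt_ode})")
        if self.newton_iters < 1:
            errs.append(f"solver.newton_iters must be >= 1, got {self.newton_iters}")
        if self.linear_solver not in ("gmres_jacobi", "direct"):
            errs.append(f"solver.linear_solver unknown: {self.linear_solver!r}")
        if len(tuple(self.body_force)) != 3:
            errs.append("solver.body_force must be a 3-vector")
        return errs


def _det3(F):
    """Determinant of batched 3x3 matrices (much faster than np.linalg.det)."""
    return (F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
            - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
            + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]))


def _inv3(F, det):
    """Inverse of batched 3x3 matrices via the adjugate."""
    inv = np.empty_like(F)
    inv[..., 0, 0] = F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1]
    inv[..., 0, 1] = F[..., 0, 2] * F[..., 2, 1] - F[..., 0, 1] * F[..., 2, 2]
    inv[..., 0, 2] = F[..., 0, 1] * F[..., 1, 2] - F[..., 0, 2] * F[..., 1, 1]
    inv[..., 1, 0] = F[..., 1, 2] * F[..., 2, 0] - F[..., 1, 0] * F[..., 2, 2]
    inv[..., 1, 1] = F[..., 0, 0] * F[..., 2, 2] - F[..., 0, 2] * F[..., 2, 0]
    inv[..., 1, 2] = F[..., 0, 2] * F[..., 1, 0] - F[..., 0, 0] * F[..., 1, 2]
    inv[..., 2, 0] = F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0]
    inv[..., 2, 1] = F[..., 0, 1] * F[..., 2, 0] - F[..., 0, 0] * F[..., 2, 1]
    inv[..., 2, 2] = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    return inv / det[..., None, None]


@dataclass
class CoupledSystem:
    """Assembled sparse linear operator and residual right-hand side.

    For the coupled mode the unknown ordering is (dx, dy, dz, dv) per node,
    i.e. degree of freedom ``4 * node + component``.
    """

    matrix: sp.spmatrix
    rhs: np.ndarray


def solve_linear(system: CoupledSystem, config: SolverConfig) -> np.ndarray:
    """Solve the assembled system for the increment vector.

    ``gmres_jacobi`` applies restarted GMRES with a Jacobi (diagonal)
    preconditioner to relative residual ``gmres_tol``; ``direct`` is an exact
    sparse LU factorization.  Raises :class:`WellPosednessError` on a zero
    diagonal (missing essential boundary conditions) and
    :class:`LinearSolverError` (carrying the residual history) on
    non-convergence or factorization breakdown.
    """
    A = system.matrix.tocsr()
    b = np.asarray(system.rhs, dtype=float)
    diag = A.diagonal()
    if np.any(diag == 0.0):
        raise WellPosednessError(
            "zero diagonal in assembled operator: the problem is "
            "underconstrained (are any nodes fixed?)")
    if config.linear_solver == "direct":
        try:
            return spla.splu(A.tocsc()).solve(b)
        except RuntimeError as exc:  # singular factorization
            raise LinearSolverError(f"direct solve failed: {exc}") from exc
    M = sp.diags(1.0 / diag)
    residuals: list[float] = []
    x, info = spla.gmres(A, b, M=M, rtol=config.gmres_tol, atol=0.0,
                         restart=min(config.gmres_restart, A.shape[0]),
                         maxiter=config.gmres_maxiter,
                         callback=residuals.append, callback_type="pr_norm")
    if info != 0:
        raise LinearSolverError(
            f"GMRES stagnated after {len(residuals)} iterations "
            f"(last relative residual "
            f"{residuals[-1] if residuals else float('nan'):.3e})",
            residuals)
    return x


class CoupledStepper:
    """Owns the simulation state and advances it one PDE step at a time.

    Parameters
    ----------
    mesh : Mesh
    ionic, tension, material, solver : parameter blocks (defaults used if None)
    mode : "coupled" or "ep_only" (mechanics frozen at the reference geometry)
    stim_nodes : node indices receiving the stimulus current
    stim_onset : ms
    """

    def __init__(self, mesh: Mesh, ionic: IonicParams = None,
                 tension: ActiveTensionParams = None,
                 material: MaterialParams = None,
                 solver: SolverConfig = None,
                 mode: str = "coupled",
                 stim_nodes=(), stim_onset: float = 0.0):
        if mode not in ("coupled", "ep_only"):
            raise ValueError(f"mode must be 'coupled' or 'ep_only', got {mode!r}")
        self.mesh = mesh
        self.ionic = ionic or IonicParams()
        self.tension = tension or ActiveTensionParams()
        self.material = material or MaterialParams()
        self.solver = solver or SolverConfig()
        self.mode = mode
        self.stim_onset = float(stim_onset)

        n = mesh.n_nodes
        self.cells = resting_state((n,))
        self.t_a = np.zeros(n)
        self.stretch_node = np.ones(n)
        self.v_star = self.cells.v.copy()
        self.residual_log: list[float] = []

        self.stim_mask = np.zeros(n, dtype=bool)
        self.stim_mask[np.asarray(stim_nodes, dtype=int)] = True
        self._scar_elem = mesh.scar_element_mask()
        self._active = ~mesh.scar_node_mask()
        self._scar_nodes = np.flatnonzero(~self._active)

        # reference-configuration quadrature data
        self.detJref, self.dNdX = mesh.reference_jacobians()
        edge = mesh.X_ref[mesh.hexes[:, 1]] - mesh.X_ref[mesh.hexes[:, 0]]
        self._fd_h = 1e-5 * float(np.linalg.norm(edge, axis=1).mean())
        self._elem_ids = np.arange(mesh.n_elems)
        self._a0_col = mesh.a0_field[:, None, :, None]  # (E, 1, 3, 1)

        # global dof index maps
        hx = mesh.hexes
        self.vdof = 4 * np.arange(n) + 3
        mdofs = (4 * hx[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
        self.mdofs = mdofs                                     # (E, 24)
        self._mrows = np.repeat(mdofs, 24, axis=1).ravel()
        self._mcols = np.tile(mdofs, (1, 24)).ravel()
        vdofs_e = 4 * hx + 3                                   # (E, 8)
        self._vrows = np.repeat(vdofs_e, 8, axis=1).ravel()
        self._vcols = np.tile(vdofs_e, (1, 8)).ravel()
        self._nrows8 = np.repeat(hx, 8, axis=1).ravel()        # for N x N blocks
        self._ncols8 = np.tile(hx, (1, 8)).ravel()

        self.pinned = np.zeros(4 * n, dtype=bool)
        for c in range(3):
            self.pinned[4 * mesh.fixed_nodes + c] = True
        if mesh.fixed_dofs.size:
            self.pinned[4 * mesh.fixed_dofs[:, 0] + mesh.fixed_dofs[:, 1]] = True
        # scar nodes carry no membrane dynamics: hold their voltage rows
        self.pinned[4 * self._scar_nodes + 3] = True

        self._ep_cache = None

    # ------------------------------------------------------------------ #
    # reaction (ODE) stage
    # ------------------------------------------------------------------ #

    def reaction_substeps(self, t: float):
        """Advance cell states and active tension over one PDE window.

        Forward-Euler substeps at every non-scar node; scar nodes are held at
        rest.  The tension ODE is advanced simultaneously with the ionic
        state (both use the pre-substep voltage).
        """
        dt = self.solver.dt_ode
        act = self._active
        sub = CellState(*(getattr(self.cells, nm)[act] for nm in STATE_NAMES))
        ta = self.t_a[act]
        stretch = self.stretch_node[act]
        smask = self.stim_mask[act]
        for i in range(self.solver.n_substeps()):
            ts = t + i * dt
            amp = stimulus_waveform(ts, self.stim_onset, self.ionic)
            stim = np.where(smask, amp, 0.0)
            v_old = sub.v
            try:
                sub = step_cell(sub, self.ionic, stretch=stretch,
                                stim=stim, dt=dt)
            except BlowUpError as exc:
                cur = ionic_currents(
                    CellState(*(getattr(sub, nm) for nm in STATE_NAMES)),
                    self.ionic, stretch=stretch, stim=stim)
                vn = sub.v - dt * cur.i_total / self.ionic.c_m
                bad = np.flatnonzero(np.abs(vn) > 500.0)
                ids = np.flatnonzero(act)[bad[:5]]
                raise BlowUpError(
                    f"membrane potential blew up at t = {ts:.3f} ms, "
                    f"node(s) {ids.tolist()}") from exc
            ta = step_tension(ta, v_old, dt, self.tension)
        for nm in STATE_NAMES:
            getattr(self.cells, nm)[act] = getattr(sub, nm)
        self.t_a[act] = ta

    # ------------------------------------------------------------------ #
    # kinematics and element quantities
    # ------------------------------------------------------------------ #

    def _kinematics(self, x=None):
        """Kinematics at every Gauss point of every element."""
        xe = (self.mesh.x_cur if x is None else x)[self.mesh.hexes]
        F = np.einsum("eai,egaj->egij", xe, self.dNdX)
        return compute_kinematics(F, self.mesh.a0_field[:, None, :],
                                  element_ids=self._elem_ids)

    def nodal_stretch(self) -> np.ndarray:
        """Element-mean fiber stretch averaged to nodes (for I_sac)."""
        kin = self._kinematics()
        es = kin.stretch.mean(axis=1)
        num = np.zeros(self.mesh.n_nodes)
        cnt = np.zeros(self.mesh.n_nodes)
        np.add.at(num, self.mesh.hexes.ravel(), np.repeat(es, 8))
        np.add.at(cnt, self.mesh.hexes.ravel(), 1.0)
        return num / cnt

    def _ta_gp(self) -> np.ndarray:
        """Nodal active tension interpolated to Gauss points; zero in scar."""
        ta = np.einsum("ga,ea->eg", hex8.N_GP, self.t_a[self.mesh.hexes])
        ta[self._scar_elem] = 0.0
        return ta

    def _geometry_at(self, xe):
        """Batched per-Gauss-point geometry of the current configuration.

        Returns ``(detF, dNdx, w, kappa, B)``: total-deformation determinant,
        current-configuration shape gradients, quadrature weights (current
        volume), deformed structural tensor and squared fiber stretch.
        """
        # F_ij = sum_a x[a,i] dN_a/dX_j
        F = np.matmul(np.swapaxes(xe, 1, 2)[:, None], self.dNdX)
        detF = _det3(F)
        if np.any(detF <= 0.0):
            bad = sorted(set(np.argwhere(detF <= 0.0)[:, 0].tolist()))
            raise InvertedElementError(
                f"inverted element(s) {bad[:10]} in the current "
                "configuration; consider reducing dt_pde")
        Finv = _inv3(F, detF)
        dNdx = np.matmul(self.dNdX, Finv)
        w = hex8.GAUSS_W[None, :] * self.detJref * detF
        a = np.matmul(F, self._a0_col)[..., 0]          # (E, G, 3)
        B = np.einsum("egi,egi->eg", a, a)
        kappa = a[..., :, None] * a[..., None, :]
        return F, detF, dNdx, w, kappa, B

    def _mech_force(self, xe, ta_gp, geom=None):
        """Internal-minus-external nodal force (E, 8, 3) at element coords xe."""
        if geom is None:
            geom = self._geometry_at(xe)
        F, detF, dNdx, w, kappa, B = geom
        m = self.material
        iso = 0.5 * m.chi * (2.0 * np.log(detF)) - m.zeta
        fib = 2.0 * m.xi * (B > 1.0) * (B - 1.0) + ta_gp
        p = np.matmul(F, np.swapaxes(F, -1, -2))
        sig = m.zeta * p + fib[..., None, None] * kappa
        sig[..., 0, 0] += iso
        sig[..., 1, 1] += iso
        sig[..., 2, 2] += iso
        f = (w[..., None, None] * np.matmul(dNdx, sig)).sum(axis=1)
        b = np.asarray(self.solver.body_force, dtype=float)
        if np.any(b):
            f = f - np.einsum("eg,ga,i->eai", w, hex8.N_GP, b)
        return f, geom

    def _voltage_blocks(self, kappa, dNdx, w):
        """Consistent mass and diffusion stiffness element blocks (E, 8, 8)."""
        m = self.material
        D = m.d_iso * np.broadcast_to(np.eye(3), kappa.shape).copy() \
            + m.d_ani * kappa
        D[self._scar_elem] = 0.0
        Me = np.einsum("eg,ga,gb->eab", w, hex8.N_GP, hex8.N_GP)
        Ke = np.einsum("eg,egai,egij,egbj->eab", w, dNdx, D, dNdx)
        return Me, Ke

    def _global_vm(self, Me, Ke):
        n = self.mesh.n_nodes
        Mg = sp.coo_matrix((Me.ravel(), (self._nrows8, self._ncols8)),
                           shape=(n, n)).tocsr()
        Kg = sp.coo_matrix((Ke.ravel(), (self._nrows8, self._ncols8)),
                           shape=(n, n)).tocsr()
        return Mg, Kg

    # ------------------------------------------------------------------ #
    # assembly and step
    # ------------------------------------------------------------------ #

    def assemble_coupled(self) -> CoupledSystem:
        """Assemble the linearized 4N x 4N operator and residual."""
        self.mesh.require_fixed_nodes()
        mesh = self.mesh
        n = mesh.n_nodes
        xe = mesh.x_cur[mesh.hexes]
        ta_gp = self._ta_gp()

        f0, geom = self._mech_force(xe, ta_gp)
        _, _, dNdx, w, kappa, _ = geom
        E = mesh.n_elems
        K24 = np.empty((E, 24, 24))
        h = self._fd_h
        # central differences: the thin-tissue tangent has soft modes several
        # orders below its largest entries, which forward differences would
        # bury in truncation noise
        for ld in range(24):
            a, i = divmod(ld, 3)
            xp = xe.copy()
            xp[:, a, i] += h
            fp, _ = self._mech_force(xp, ta_gp)
            xm = xe.copy()
            xm[:, a, i] -= h
            fm, _ = self._mech_force(xm, ta_gp)
            K24[:, :, ld] = (fp - fm).reshape(E, 24) / (2 * h)

        Me, Ke = self._voltage_blocks(kappa, dNdx, w)
        Mg, Kg = self._global_vm(Me, Ke)
        dt = self.solver.dt_pde
        v = self.cells.v
        R_v = Mg @ ((v - self.v_star) / dt) + Kg @ v
        Avv = Me / dt + Ke

        rhs = np.zeros(4 * n)
        np.subtract.at(rhs, self.mdofs.ravel(), f0.reshape(E, 24).ravel())
        rhs[self.vdof] = -R_v

        rows = np.concatenate([self._mrows, self._vrows])
        cols = np.concatenate([self._mcols, self._vcols])
        data = np.concatenate([K24.ravel(), Avv.ravel()])
        keep = ~self.pinned[rows]
        pinned_dofs = np.flatnonzero(self.pinned)
        rows = np.concatenate([rows[keep], pinned_dofs])
        cols = np.concatenate([cols[keep], pinned_dofs])
        data = np.concatenate([data[keep], np.ones(pinned_dofs.size)])
        rhs[pinned_dofs] = 0.0
        A = sp.coo_matrix((data, (rows, cols)), shape=(4 * n, 4 * n)).tocsr()
        return CoupledSystem(matrix=A, rhs=rhs)

    def _ep_operator(self):
        """Cached voltage-only operator on the frozen reference geometry."""
        if self._ep_cache is None:
            _, _, dNdx, w, kappa, _ = self._geometry_at(
                self.mesh.x_cur[self.mesh.hexes])
            Me, Ke = self._voltage_blocks(kappa, dNdx, w)
            Mg, Kg = self._global_vm(Me, Ke)
            A = (Mg / self.solver.dt_pde + Kg).tocsr()
            if self._scar_nodes.size:
                keep = np.ones(A.shape[0])
                keep[self._scar_nodes] = 0.0
                A = (sp.diags(keep) @ A
                     + sp.diags(1.0 - keep)).tocsr()
            lu = spla.splu(A.tocsc()) \
                if self.solver.linear_solver == "direct" else None
            self._ep_cache = (A, Kg, Mg, lu)
        return self._ep_cache

    def mass_matrix(self) -> sp.csr_matrix:
        """Global consistent mass matrix of the voltage field (current geometry)."""
        _, _, dNdx, w, kappa, _ = self._geometry_at(
            self.mesh.x_cur[self.mesh.hexes])
        Me, _ = self._voltage_blocks(kappa, dNdx, w)
        Mg, _ = self._global_vm(Me, np.zeros_like(Me))
        return Mg

    def step(self, t: float, skip_reaction: bool = False):
        """Advance the full coupled state over [t, t + dt_pde]."""
        if self.mode == "coupled":
            self.mesh.require_fixed_nodes()
            self.stretch_node = self.nodal_stretch()
        if not skip_reaction:
            self.reaction_substeps(t)
        self.v_star = self.cells.v.copy()

        if self.mode == "ep_only":
            A, Kg, Mg, lu = self._ep_operator()
            rhs = -(Kg @ self.v_star)
            if lu is not None:
                dv = lu.solve(rhs)
            else:
                dv = solve_linear(CoupledSystem(matrix=A, rhs=rhs), self.solver)
            self.cells.v = self.v_star + dv
            self.residual_log.append(float(np.linalg.norm(rhs)))
        else:
            for _ in range(self.solver.newton_iters):
                system = self.assemble_coupled()
                inc = solve_linear(system, self.solver)
                inc4 = inc.reshape(-1, 4)
                self.mesh.x_cur += inc4[:, :3]
                self.cells.v = self.cells.v + inc4[:, 3]
                self.residual_log.append(float(np.linalg.norm(system.rhs)))
        if np.any(np.abs(self.cells.v) > 500.0):
            raise BlowUpError(
                f"membrane potential exceeded 500 mV after the PDE stage "
                f"at t = {t:.3f} ms")
        return self

    #: alias matching the operator-splitting step nomenclature
    step_coupled = step
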