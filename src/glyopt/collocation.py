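"""Pseudo-spectral (Legendre-Gauss-Lobatto) transcription machinery.

An optimal-control problem on a horizon is discretized by representing
states and controls with Lagrange interpolating polynomials on
Legendre-Gauss-Lobatto (LGL) nodes.  The dynamics become algebraic
*defect* constraints (the differentiation matrix applied to the node
states must equal the scaled right-hand side at each node), the running
cost becomes a Gauss-Lobatto quadrature, and the whole problem becomes a
finite-dimensional nonlinear program.

LGL nodes are used (rather than Gauss or Radau points) so that both
endpoints of each phase are nodes: initial conditions, phase-linkage
conditions and endpoint bounds then bind directly on decision variables.
A horizon with an impulsive meal is split into phases at the meal time;
the state is linked across the boundary with a prescribed jump in the
solid-stomach compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.optimize import root


# ---------------------------------------------------------------------
# nodes, weights, differentiation
# ---------------------------------------------------------------------

def lgl_nodes_weights(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Legendre-Gauss-Lobatto nodes and quadrature weights of order N.

    Returns ``N + 1`` nodes in [-1, 1] including both endpoints, and
    weights exact for polynomials up to degree ``2N - 1``.
    """
    if N < 1:
        raise ValueError("LGL order must be at least 1")
    if N == 1:
        return np.array([-1.0, 1.0]), np.array([1.0, 1.0])
    # interior nodes are the roots of P_N'(tau)
    cN = np.zeros(N + 1)
    cN[N] = 1.0
    interior = npleg.legroots(npleg.legder(cN))
    nodes = np.concatenate([[-1.0], np.sort(interior), [1.0]])
    PN = npleg.legval(nodes, cN)
    weights = 2.0 / (N * (N + 1) * PN ** 2)
    return nodes, weights


def differentiation_matrix(nodes: np.ndarray) -> np.ndarray:
    """First-derivative matrix of the Lagrange basis on arbitrary nodes.

    ``D[k, i]`` is the derivative of the i-th Lagrange cardinal
    polynomial at node k, computed with barycentric weights; rows sum to
    zero (the derivative of a constant vanishes) and the matrix
    differentiates polynomials up to the nodal degree exactly.
    """
    tau = np.asarray(nodes, dtype=float)
    n = tau.size
    diff = tau[:, None] - tau[None, :]
    if np.any(np.abs(diff + np.eye(n)) < 1e-14):
        raise ValueError("collocation nodes must be distinct")
    np.fill_diagonal(diff, 1.0)
    # barycentric weights
    w = 1.0 / np.prod(diff, axis=1)
    D = (w[None, :] / w[:, None]) / diff
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


@dataclass
class CollocationGrid:
    """Order-N LGL grid: nodes, quadrature weights, differentiation matrix."""

    N: int
    nodes: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)
    D: np.ndarray = field(init=False)

    def __post_init__(self):
        self.nodes, self.weights = lgl_nodes_weights(self.N)
        self.D = differentiation_matrix(self.nodes)


def map_time(tau, t0: float, tf: float):
    """Affine map from the reference interval [-1, 1] to [t0, tf] (min)."""
    if tf <= t0:
        raise ValueError("tf must exceed t0")
    return 0.5 * (tf - t0) * np.asarray(tau) + 0.5 * (tf + t0)


# ---------------------------------------------------------------------
# multi-phase transcription
# ---------------------------------------------------------------------

@dataclass
class PhaseSpec:
    """One smooth phase of the horizon.

    ``dynamics(X, U) -> (nx, M)`` and ``dynamics_jac(X, U) ->
    ((M, nx, nx), (nx, nu))`` evaluate the right-hand side and its
    Jacobians at all nodes at once.  ``jump`` is added to the final state
    of the *previous* phase to form this phase's initial state (the
    impulsive-meal linkage); zero for interior continuity.
    """

    t_start: float
    t_end: float
    N: int
    dynamics: Callable
    dynamics_jac: Callable
    jump: np.ndarray | None = None

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("phase must have positive duration")
        self.grid = CollocationGrid(self.N)
        self.times = map_time(self.grid.nodes, self.t_start, self.t_end)
        self.half = 0.5 * (self.t_end - self.t_start)


class NLPProblem:
    """A transcribed optimal-control problem ready for an NLP solver.

    Decision vector ``z`` stacks, phase by phase, the scaled states at
    the nodes (row-major ``(N+1, nx)``) followed by the scaled controls
    ``(N+1, nu)``.  Holds the objective with gradient, the defect and
    linkage equality constraints with Jacobians, quadrature (total-dose)
    inequality constraints, and simple bounds.
    """

    def __init__(self, phases: Sequence[PhaseSpec], nx: int, nu: int,
                 integrand: Callable, integrand_grad: Callable,
                 x0: np.ndarray,
                 x_bounds: tuple[np.ndarray, np.ndarray],
                 u_bounds: tuple[np.ndarray, np.ndarray],
                 x_scale: np.ndarray, u_scale: np.ndarray,
                 quad_caps: Sequence[tuple[int, float]] = ()):
        self.phases = list(phases)
        self.nx, self.nu = nx, nu
        self.integrand = integrand
        self.integrand_grad = integrand_grad
        self.x0 = np.asarray(x0, dtype=float)
        self.xL, self.xU = (np.asarray(b, dtype=float) for b in x_bounds)
        self.uL, self.uU = (np.asarray(b, dtype=float) for b in u_bounds)
        if np.any(self.xL > self.xU) or np.any(self.uL > self.uU):
            raise ValueError("lower bounds exceed upper bounds")
        self.x_scale = np.asarray(x_scale, dtype=float)
        self.u_scale = np.asarray(u_scale, dtype=float)
        self.quad_caps = list(quad_caps)

        self._offsets = []
        off = 0
        for ph in self.phases:
            m = ph.N + 1
            self._offsets.append(off)
            off += m * (nx + nu)
        self.nz = off
        self.n_defects = sum(ph.N * nx for ph in self.phases)
        self.n_link = (len(self.phases) - 1) * nx
        self.n_init = nx

    # -- packing -------------------------------------------------------

    def unpack(self, z: np.ndarray):
        """Split ``z`` into per-phase (states (nx, N+1), controls (nu, N+1))."""
        out = []
        for ph, off in zip(self.phases, self._offsets):
            m = ph.N + 1
            X = z[off:off + m * self.nx].reshape(m, self.nx).T * self.x_scale[:, None]
            U = (z[off + m * self.nx: off + m * (self.nx + self.nu)]
                 .reshape(m, self.nu).T * self.u_scale[:, None])
            out.append((X, U))
        return out

    def pack(self, XU) -> np.ndarray:
        z = np.empty(self.nz)
        for (X, U), ph, off in zip(XU, self.phases, self._offsets):
            m = ph.N + 1
            z[off:off + m * self.nx] = (X / self.x_scale[:, None]).T.ravel()
            z[off + m * self.nx: off + m * (self.nx + self.nu)] = \
                (U / self.u_scale[:, None]).T.ravel()
        return z

    @property
    def node_times(self) -> np.ndarray:
        return np.concatenate([ph.times for ph in self.phases])

    # -- objective -----------------------------------------------------

    def objective(self, z: np.ndarray) -> float:
        J = 0.0
        for (X, U), ph in zip(self.unpack(z), self.phases):
            J += ph.half * float(np.dot(ph.grid.weights, self.integrand(X, U)))
        return J

    def objective_grad(self, z: np.ndarray) -> np.ndarray:
        g = np.zeros(self.nz)
        for (X, U), ph, off in zip(self.unpack(z), self.phases, self._offsets):
            m = ph.N + 1
            dFdx, dFdu = self.integrand_grad(X, U)      # (nx, M), (nu, M)
            gx = ph.half * ph.grid.weights[None, :] * dFdx * self.x_scale[:, None]
            gu = ph.half * ph.grid.weights[None, :] * dFdu * self.u_scale[:, None]
            g[off:off + m * self.nx] = gx.T.ravel()
            g[off + m * self.nx: off + m * (self.nx + self.nu)] = gu.T.ravel()
        return g

    # -- equality constraints (defects + linkage) ----------------------

    def eq_constraints(self, z: np.ndarray) -> np.ndarray:
        XU = self.unpack(z)
        parts = []
        for (X, U), ph in zip(XU, self.phases):
            F = ph.dynamics(X, U)                       # (nx, N+1)
            defect = X @ ph.grid.D.T - ph.half * F      # (nx, N+1)
            parts.append((defect[:, 1:] / self.x_scale[:, None]).T.ravel())
        for k in range(1, len(self.phases)):
            Xp, _ = XU[k - 1]
            Xn, _ = XU[k]
            jump = (self.phases[k].jump if self.phases[k].jump is not None
                    else np.zeros(self.nx))
            parts.append((Xn[:, 0] - Xp[:, -1] - jump) / self.x_scale)
        # initial condition as an explicit equality (not a pinned bound)
        X0, _ = XU[0]
        parts.append((X0[:, 0] - self.x0) / self.x_scale)
        return np.concatenate(parts)

    def eq_jacobian(self, z: np.ndarray) -> np.ndarray:
        XU = self.unpack(z)
        Jall = np.zeros((self.n_defects + self.n_link + self.n_init, self.nz))
        row = 0
        for (X, U), ph, off in zip(XU, self.phases, self._offsets):
            m = ph.N + 1
            Jx, Ju = ph.dynamics_jac(X, U)              # (m, nx, nx), (nx, nu)
            D = ph.grid.D
            s = self.x_scale
            # rows: defect (k, i_state) for k = 1..N ; cols: z entries
            for k in range(1, m):
                r0 = row + (k - 1) * self.nx
                # derivative w.r.t. states at node j: D[k, j] I - half * Jx[k] (j == k)
                for j in range(m):
                    c0 = off + j * self.nx
                    block = np.zeros((self.nx, self.nx))
                    if D[k, j] != 0.0:
                        block += D[k, j] * np.eye(self.nx)
                    if j == k:
                        block -= ph.half * Jx[k]
                    # scale: rows / s, cols * x_scale
                    Jall[r0:r0 + self.nx, c0:c0 + self.nx] = \
                        block * (self.x_scale[None, :] / s[:, None])
                cu = off + m * self.nx + k * self.nu
                Jall[r0:r0 + self.nx, cu:cu + self.nu] = \
                    -ph.half * Ju * (self.u_scale[None, :] / s[:, None])
            row += ph.N * self.nx
        for k in range(1, len(self.phases)):
            off_p = self._offsets[k - 1]
            off_n = self._offsets[k]
            m_p = self.phases[k - 1].N + 1
            iN = off_p + (m_p - 1) * self.nx
            i0 = off_n
            Jall[row:row + self.nx, i0:i0 + self.nx] = np.eye(self.nx)
            Jall[row:row + self.nx, iN:iN + self.nx] = -np.eye(self.nx)
            row += self.nx
        Jall[row:row + self.nx, 0:self.nx] = np.eye(self.nx)
        return Jall

    # -- inequality (total-dose quadrature caps) -----------------------

    def _quad_row(self, control_index: int) -> np.ndarray:
        """Gradient row of the total-dose quadrature for one control."""
        rowv = np.zeros(self.nz)
        for ph, off in zip(self.phases, self._offsets):
            m = ph.N + 1
            for k in range(m):
                c = off + m * self.nx + k * self.nu + control_index
                rowv[c] = ph.half * ph.grid.weights[k] * self.u_scale[control_index]
        return rowv

    def total_dose(self, z: np.ndarray, control_index: int) -> float:
        tot = 0.0
        for (X, U), ph in zip(self.unpack(z), self.phases):
            tot += ph.half * float(np.dot(ph.grid.weights, U[control_index]))
        return tot

    def ineq_constraints(self):
        """List of (fun, jac) with fun(z) >= 0 convention."""
        cons = []
        for ci, cap in self.quad_caps:
            rowv = self._quad_row(ci)
            cons.append((lambda z, ci=ci, cap=cap: cap - self.total_dose(z, ci),
                         lambda z, rowv=rowv: -rowv))
        return cons

    # -- bounds --------------------------------------------------------

    def bounds(self) -> list[tuple[float, float]]:
        bds = []
        for ph, off in zip(self.phases, self._offsets):
            m = ph.N + 1
            for k in range(m):
                for i in range(self.nx):
                    lo = self.xL[i] / self.x_scale[i]
                    hi = self.xU[i] / self.x_scale[i]
                    if ph is self.phases[0] and k == 0:
                        # keep the pinned initial state inside the box (it
                        # is fixed by an equality constraint, not bounds)
                        lo = min(lo, self.x0[i] / self.x_scale[i])
                        hi = max(hi, self.x0[i] / self.x_scale[i])
                    bds.append((lo, hi))
            for k in range(m):
                for i in range(self.nu):
                    bds.append((self.uL[i] / self.u_scale[i],
                                self.uU[i] / self.u_scale[i]))
        return bds


def transcribe(phases: Sequence[PhaseSpec], nx: int, nu: int,
               integrand: Callable, integrand_grad: Callable,
               x0: np.ndarray, x_bounds, u_bounds,
               x_scale=None, u_scale=None, quad_caps=()) -> NLPProblem:
    """Assemble the multi-phase LGL transcription into an NLP."""
    if x_scale is None:
        x_scale = np.ones(nx)
    if u_scale is None:
        u_scale = np.ones(nu)
    return NLPProblem(phases, nx, nu, integrand, integrand_grad, x0,
                      x_bounds, u_bounds, x_scale, u_scale, quad_caps)


# ---------------------------------------------------------------------
# defect solve for a fixed control (feasibility oracle / warm start)
# ---------------------------------------------------------------------

def _damped_newton(resid, jac, z0, tol=1e-10, maxiter=40):
    """Nonmonotone Newton iteration; returns None on divergence.

    Full Newton steps are taken (transient residual growth is tolerated:
    the collocation defect system converges quadratically near the
    solution but a strict line search stagnates far from it); the
    iteration aborts if the residual becomes non-finite or grows by
    orders of magnitude, keeping the best iterate seen.
    """
    z = z0.copy()
    r = resid(z)
    n0 = np.linalg.norm(r)
    best_z, best_n = z, n0
    for _ in range(maxiter):
        if np.max(np.abs(r)) < 1e-9:
            return z
        try:
            dz = np.linalg.solve(jac(z), -r)
        except np.linalg.LinAlgError:
            break
        z = z + dz
        r = resid(z)
        n = np.linalg.norm(r)
        if not np.isfinite(n) or n > 1e4 * (n0 + 1.0):
            break
        if n < best_n:
            best_z, best_n = z.copy(), n
    return best_z if np.max(np.abs(resid(best_z))) < 1e-6 else None


def _rk4_node_guess(ph: PhaseSpec, x_start: np.ndarray, U: np.ndarray,
                    substeps: int = 8) -> np.ndarray:
    """Coarse fixed-step RK4 prediction of the node states of one phase.

    Only used to seed the Newton iteration of :func:`solve_defects`; the
    converged defect solution does not depend on the seed.
    """
    nx = x_start.size
    m = ph.N + 1
    X = np.empty((nx, m))
    X[:, 0] = x_start
    x = x_start.copy()
    for k in range(1, m):
        ta, tb = ph.times[k - 1], ph.times[k]
        uk = 0.5 * (U[:, k - 1] + U[:, k])
        h = (tb - ta) / substeps
        f = lambda y: ph.dynamics(y[:, None], uk[:, None])[:, 0]
        for _ in range(substeps):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        X[:, k] = x
    return X

def phase_system_matrices(ph: PhaseSpec, X: np.ndarray, U: np.ndarray):
    """Derivatives of one phase's defect system at (X, U).

    For the defect residuals R (nodes 1..N, node-major) returns

    * ``A`` = dR/d(free states)   (N*nx, N*nx),
    * ``B`` = dR/d(node controls) (N*nx, (N+1)*nu), node-major columns,
    * ``C`` = dR/d(start state)   (N*nx, nx).

    Used for implicit differentiation of the states with respect to the
    controls when the defect system is solved exactly (reduced-space
    optimization), and for Newton iterations.
    """
    nx = X.shape[0]
    m = ph.N + 1
    nu = U.shape[0]
    D = ph.grid.D
    Jx, Ju = ph.dynamics_jac(X, U)
    A = np.zeros((nx * (m - 1), nx * (m - 1)))
    B = np.zeros((nx * (m - 1), nu * m))
    C = np.zeros((nx * (m - 1), nx))
    for k in range(1, m):
        r = (k - 1) * nx
        for j in range(1, m):
            blk = D[k, j] * np.eye(nx)
            if j == k:
                blk = blk - ph.half * Jx[k]
            A[r:r + nx, (j - 1) * nx:j * nx] = blk
        B[r:r + nx, k * nu:(k + 1) * nu] = -ph.half * Ju
        C[r:r + nx, :] = D[k, 0] * np.eye(nx)
    return A, B, C


def solve_defects(phases: Sequence[PhaseSpec], x0: np.ndarray,
                  controls: Sequence[np.ndarray],
                  guess: Sequence[np.ndarray] | None = None,
                  tol: float = 1e-10) -> list[np.ndarray]:
    """States satisfying the collocation defects for *fixed* node controls.

    For each phase in turn, solves the square nonlinear system (defects
    at nodes 1..N with the initial node pinned) by Newton iteration with
    the analytic Jacobian.  This is collocation used purely as an
    implicit integrator; comparing it with an adaptive time-stepper is
    the transcription's correctness oracle.
    """
    nx = x0.size
    out = []
    x_start = np.asarray(x0, dtype=float)
    for idx, ph in enumerate(phases):
        if ph.jump is not None:
            x_start = x_start + ph.jump
        m = ph.N + 1
        U = np.asarray(controls[idx], dtype=float)
        D = ph.grid.D

        def unpack_z(zf):
            X = np.empty((nx, m))
            X[:, 0] = x_start
            X[:, 1:] = zf.reshape(m - 1, nx).T
            return X

        def resid(zf):
            X = unpack_z(zf)
            F = ph.dynamics(X, U)
            defect = X @ D.T - ph.half * F
            return defect[:, 1:].T.ravel()

        def jac(zf):
            X = unpack_z(zf)
            Jx, _ = ph.dynamics_jac(X, U)
            J = np.zeros((nx * (m - 1), nx * (m - 1)))
            for k in range(1, m):
                for j in range(1, m):
                    blk = D[k, j] * np.eye(nx)
                    if j == k:
                        blk = blk - ph.half * Jx[k]
                    J[(k - 1) * nx:k * nx, (j - 1) * nx:j * nx] = blk
            return J

        if guess is not None:
            z0 = np.asarray(guess[idx])[:, 1:].T.ravel()
        else:
            z0 = _rk4_node_guess(ph, x_start, U)[:, 1:].T.ravel()
        z = _damped_newton(resid, jac, z0, tol=tol)
        if z is None and guess is not None:
            # retry from the integration-based seed
            z = _damped_newton(
                resid, jac, _rk4_node_guess(ph, x_start, U)[:, 1:].T.ravel(),
                tol=tol)
        if z is None:
            raise RuntimeError(f"defect solve failed in phase {idx}")
        X = unpack_z(z)
        out.append(X)
        x_start = X[:, -1]
    return out
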