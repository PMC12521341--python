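"""Optimal control of multiplicative-control cell-population models.

The problem is the fixed-horizon minimisation of

    J(u) = 1/2 [ x(T)^T M x(T) + int_0^T ( x^T Q x + u^T R u ) dt ]

subject to the semi-linear dynamics of :mod:`celldose.model` and the box
constraint ``0 <= u_k <= 1``.  First-order (Pontryagin) conditions couple the
state to a co-state ``lambda`` via the Hamiltonian

    H = 1/2 (x^T Q x + u^T R u) + lambda . dx/dt,

with adjoint dynamics ``dlambda/dt = -dH/dx``, transversality
``lambda(T) = M x(T)`` and stationarity ``dH/du = 0`` projected onto the box.
Because the dynamics are quadratic in ``u``, H is an exact quadratic in ``u``
at fixed ``(x, lambda)``:

    dH/du = G u + b,   G = R + sum_ij x_i lambda_j (D^ij + D^ij^T),
                       b = (B + sum_i x_i C_i)^T lambda,

so the box-constrained minimiser is the clipped unconstrained stationary
point ``-G^{-1} b`` when G is diagonal, refined by coordinate descent over
the box otherwise.  Eliminating ``u`` pointwise turns the two-point boundary
value problem in ``(x, lambda)`` into a closed 2n-dimensional BVP, solved by
collocation (:func:`scipy.integrate.solve_bvp`, the residual-controlled
fourth-order scheme in the bvp4c family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp

from . import model as _model
from .model import ControlledODEModel, ModelValidationError

__all__ = [
    "CostSpec",
    "OCProblem",
    "OCSolution",
    "SolverSettings",
    "StateTrajectory",
    "SingularOptimality",
    "ConvergenceError",
    "hamiltonian",
    "adjoint_rhs",
    "stationary_control",
    "solve",
    "simulate_forward",
]

_SYMMETRY_RTOL = 1e-12


class SingularOptimality(RuntimeError):
    """The Hessian ``G`` of H in u is (numerically) singular.

    The stationarity condition then fails to determine ``u`` and the problem
    needs singular-arc / Pontryagin switching analysis, which this package
    does not perform.  Carries the offending ``(x, lam, cond)``.
    """

    def __init__(self, x, lam, cond):
        self.x = np.asarray(x)
        self.lam = np.asarray(lam)
        self.cond = float(cond)
        super().__init__(
            f"Hessian of H in u is numerically singular (cond={self.cond:.3e}); "
            "singular optimal control is out of scope"
        )


class ConvergenceError(RuntimeError):
    """BVP collocation failed to converge; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _check_quadratic_form(name, W, *, definite: bool, size: int):
    W = np.asarray(W, dtype=float)
    if W.shape != (size, size):
        raise ModelValidationError(f"{name} must be {size}x{size}, got {W.shape}")
    scale = max(1.0, float(np.abs(W).max()))
    if np.abs(W - W.T).max() > _SYMMETRY_RTOL * scale:
        raise ModelValidationError(f"{name} is not symmetric")
    eig = np.linalg.eigvalsh(W)
    if definite and eig.min() <= 0:
        raise ModelValidationError(f"{name} must be positive definite (min eig {eig.min():.3e})")
    if not definite and eig.min() < -1e-12 * scale:
        raise ModelValidationError(f"{name} must be positive semi-definite (min eig {eig.min():.3e})")
    return W


@dataclass
class CostSpec:
    """Quadratic cost: terminal ``M`` (PSD), running ``Q`` (PSD), control ``R``
    (PD) and horizon ``T`` in rescaled time.

    ``Q`` and ``R`` may be callables ``t -> matrix`` for time-varying
    penalties; every worked example uses constants.
    """

    M: np.ndarray
    Q: np.ndarray | Callable[[float], np.ndarray]
    R: np.ndarray | Callable[[float], np.ndarray]
    T: float

    def __post_init__(self):
        if self.T <= 0:
            raise ModelValidationError("horizon T must be positive")
        n = np.atleast_2d(np.asarray(self.M, dtype=float)).shape[0]
        self.M = _check_quadratic_form("M", np.atleast_2d(self.M), definite=False, size=n)
        if not callable(self.Q):
            m_ = np.atleast_2d(np.asarray(self.Q, dtype=float)).shape[0]
            self.Q = _check_quadratic_form("Q", np.atleast_2d(self.Q), definite=False, size=m_)
        if not callable(self.R):
            r_ = np.atleast_2d(np.asarray(self.R, dtype=float)).shape[0]
            self.R = _check_quadratic_form("R", np.atleast_2d(self.R), definite=True, size=r_)

    def Q_at(self, t: float) -> np.ndarray:
        return np.atleast_2d(self.Q(t)) if callable(self.Q) else self.Q

    def R_at(self, t: float) -> np.ndarray:
        return np.atleast_2d(self.R(t)) if callable(self.R) else self.R

    @property
    def time_varying(self) -> bool:
        return callable(self.Q) or callable(self.R)


@dataclass
class OCProblem:
    """A model, a cost and an initial state, with per-drug box bounds."""

    model: ControlledODEModel
    cost: CostSpec
    x0: np.ndarray
    control_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float).ravel()
        n, m = self.model.n, self.model.m
        if self.x0.shape != (n,):
            raise ModelValidationError(f"x0 must have length n={n}")
        if np.any(self.x0 < 0):
            raise ModelValidationError("x0 must be nonnegative")
        if self.control_bounds is None:
            self.control_bounds = (np.zeros(m), np.ones(m))
        lb = np.broadcast_to(np.asarray(self.control_bounds[0], float), (m,)).copy()
        ub = np.broadcast_to(np.asarray(self.control_bounds[1], float), (m,)).copy()
        if np.any(lb >= ub):
            raise ModelValidationError("control bounds must satisfy lower < upper")
        self.control_bounds = (lb, ub)
        if self.cost.M.shape[0] != n:
            raise ModelValidationError("terminal penalty M does not match state dimension")


@dataclass
class SolverSettings:
    """Collocation and control-elimination settings.

    Defaults follow the reference numerical scheme: relative tolerance 1e-3,
    boundary tolerance 1e-8, at most 5e5 collocation nodes, an initial mesh of
    101 uniform nodes, and the initial guess ``x = x0``, ``lambda = 0``.
    """

    tol: float = 1e-3
    bc_tol: float = 1e-8
    max_nodes: int = 500_000
    initial_nodes: int = 101
    singularity_cond: float = 1e10
    cd_max_sweeps: int = 20
    cd_tol: float = 1e-10
    raise_on_failure: bool = True
    verbose: int = 0


@dataclass
class StateTrajectory:
    """Forward-simulated state path with a dense interpolant."""

    t: np.ndarray
    x: np.ndarray  # (nt, n)
    sol: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def final_state(self) -> np.ndarray:
        return self.x[-1]


@dataclass
class OCSolution:
    """Converged (or diagnosed) solution of the two-point BVP."""

    t: np.ndarray  # (nt,)
    x: np.ndarray  # (nt, n)
    lam: np.ndarray  # (nt, n)
    u: np.ndarray  # (nt, m)
    J: float
    converged: bool
    stationarity_residual: float
    bvp_diagnostics: dict = field(default_factory=dict)
    problem: OCProblem | None = None
    _dense: Callable | None = None

    def control_interpolant(self) -> Callable[[float], np.ndarray]:
        """Return ``u(t)`` reconstructed from the dense (x, lambda) solution
        via the projected stationarity condition (exact elimination)."""
        if self._dense is None or self.problem is None:
            t, u = self.t, self.u

            def u_of_t(s):
                return np.array([np.interp(s, t, u[:, k]) for k in range(u.shape[1])])

            return u_of_t
        problem, dense = self.problem, self._dense
        n = problem.model.n

        def u_of_t(s):
            y = dense(np.atleast_1d(np.asarray(s, float)))
            U, _ = _stationary_batch(problem, y[:n], y[n:], float(np.atleast_1d(s)[0]))
            return U[:, 0] if np.isscalar(s) or np.ndim(s) == 0 else U.T

        return u_of_t

    def to_frame(self):
        """Trajectory as a tidy table: t, x_1..x_n, lam_1..lam_n, u_1..u_m."""
        import pandas as pd

        n, m = self.x.shape[1], self.u.shape[1]
        data = {"t": self.t}
        for i in range(n):
            data[f"x_{i + 1}"] = self.x[:, i]
        for i in range(n):
            data[f"lam_{i + 1}"] = self.lam[:, i]
        for k in range(m):
            data[f"u_{k + 1}"] = self.u[:, k]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# pointwise Pontryagin quantities
# ---------------------------------------------------------------------------


def hamiltonian(problem: OCProblem, x, u, lam, t: float = 0.0) -> float:
    """``H = 1/2 (x'Qx + u'Ru) + lam . rhs(x, u)``."""
    x = np.asarray(x, float).ravel()
    u = np.asarray(u, float).ravel()
    lam = np.asarray(lam, float).ravel()
    Q, R = problem.cost.Q_at(t), problem.cost.R_at(t)
    running = 0.5 * (x @ Q @ x + u @ R @ u)
    return float(running + lam @ _model.rhs(problem.model, x, u))


def adjoint_rhs(problem: OCProblem, x, u, lam, t: float = 0.0) -> np.ndarray:
    """``dlambda/dt = -dH/dx`` expanded for the structured dynamics:

    component i is ``-(Qx)_i - (A^T lam)_i - lam . (C_i u)
    - sum_j lam_j u^T D^ij u``.
    """
    x = np.asarray(x, float).ravel()
    u = np.asarray(u, float).ravel()
    lam = np.asarray(lam, float).ravel()
    model = problem.model
    Q = problem.cost.Q_at(t)
    lin = np.einsum("ijl,l,j->i", model.C, u, lam)
    quad = np.einsum("ijkl,k,l,j->i", model.D, u, u, lam)
    return -Q @ x - model.A.T @ lam - lin - quad


def _hessian_and_gradient_const(problem: OCProblem, X, Lam, t: float):
    """``G`` and ``b`` of ``dH/du = G u + b`` for a batch of grid points.

    ``b`` has shape (m, k).  ``G`` is returned as a single (m, m) matrix when
    it is the same at every point (no synergies, so ``G = R``), else (m, m, k).
    """
    model = problem.model
    R = problem.cost.R_at(t)
    b = model.B.T @ Lam + np.einsum("ik,ijl,jk->lk", X, model.C, Lam)
    if model.has_interactions:
        Dsym = model.symmetrised_D()
        G = R[:, :, None] + np.einsum("ik,jk,ijab->abk", X, Lam, Dsym)
    else:
        G = R
    return G, b


def _box_qp_batch(G, b, lb, ub, settings: SolverSettings):
    """Minimise ``1/2 u'Gu + b'u`` over the box, independently per column.

    Strategy: clip the unconstrained stationary point; when G has off-diagonal
    structure, refine by cyclic coordinate descent (exact 1-d box minimisation
    per coordinate, choosing the better endpoint if a diagonal entry is not
    positive).
    """
    m, k = b.shape
    if G.ndim == 2:  # Hessian shared across the batch
        cond_val = float(np.linalg.cond(G))
        if not np.isfinite(cond_val) or cond_val > settings.singularity_cond:
            raise SingularOptimality(np.full(m, np.nan), np.full(m, np.nan), cond_val)
        u = np.linalg.solve(G, -b).T  # (k, m)
        cond = np.full(k, cond_val)
        Gk = np.broadcast_to(G, (k, m, m))
    else:
        Gk = np.moveaxis(G, -1, 0)  # (k, m, m)
        cond = np.linalg.cond(Gk)
        worst = int(np.argmax(cond))
        if not np.all(np.isfinite(cond)) or cond.max() > settings.singularity_cond:
            raise SingularOptimality(
                np.full(m, np.nan), np.full(m, np.nan), cond[worst]
            )
        u = np.linalg.solve(Gk, -b.T[..., None])[..., 0]  # (k, m)
    u = np.clip(u, lb, ub)
    offdiag = Gk - Gk * np.eye(m)[None, :, :]
    if np.any(np.abs(offdiag) > 0):
        diag = np.einsum("kii->ki", Gk)  # (k, m)
        for _ in range(settings.cd_max_sweeps):
            delta = 0.0
            for j in range(m):
                r = b[j] + np.einsum("ki,ki->k", Gk[:, j, :], u) - diag[:, j] * u[:, j]
                gjj = diag[:, j]
                with np.errstate(divide="ignore", invalid="ignore"):
                    interior = np.clip(-r / gjj, lb[j], ub[j])
                # non-convex coordinate: minimum is at a box endpoint
                lo_val = 0.5 * gjj * lb[j] ** 2 + r * lb[j]
                hi_val = 0.5 * gjj * ub[j] ** 2 + r * ub[j]
                endpoint = np.where(lo_val <= hi_val, lb[j], ub[j])
                new = np.where(gjj > 0, interior, endpoint)
                delta = max(delta, float(np.abs(new - u[:, j]).max(initial=0.0)))
                u[:, j] = new
            if delta < settings.cd_tol:
                break
    return u.T, cond  # (m, k), (k,)


def _stationary_batch(problem: OCProblem, X, Lam, t: float, settings=None):
    settings = settings or SolverSettings()
    G, b = _hessian_and_gradient_const(problem, X, Lam, t)
    lb, ub = problem.control_bounds
    return _box_qp_batch(G, b, lb, ub, settings)


def stationary_control(problem: OCProblem, x, lam, t: float = 0.0, settings=None):
    """Box-projected minimiser of H over ``u`` at fixed ``(x, lam)``.

    Returns ``(u, cond)`` where ``cond`` is the condition number of the
    Hessian ``G``; raises :class:`SingularOptimality` when ``G`` is
    numerically singular rather than silently pseudo-inverting.
    """
    x = np.asarray(x, float).reshape(-1, 1)
    lam = np.asarray(lam, float).reshape(-1, 1)
    try:
        U, cond = _stationary_batch(problem, x, lam, t, settings)
    except SingularOptimality as err:
        raise SingularOptimality(x.ravel(), lam.ravel(), err.cond) from None
    return U[:, 0], float(cond[0])


def _projected_gradient_residual(problem, X, Lam, U, t):
    """Max-norm of ``u - clip(u - dH/du)`` over a batch of grid points."""
    G, b = _hessian_and_gradient_const(problem, X, Lam, t)
    grad = (G @ U if G.ndim == 2 else np.einsum("abk,bk->ak", G, U)) + b
    lb, ub = problem.control_bounds
    proj = np.clip(U - grad, lb[:, None], ub[:, None])
    return float(np.abs(U - proj).max(initial=0.0))


# ---------------------------------------------------------------------------
# boundary value solve
# ---------------------------------------------------------------------------


def _collocate_with_retries(fun, bc, T, guess, settings: SolverSettings):
    """Run solve_bvp, retrying on coarser/finer initial meshes.

    The projected control introduces kinks in the residual, and collocation
    convergence can depend on where the initial mesh places its nodes; a
    small ladder of initial mesh sizes recovers the occasional stalled cell.
    """
    n0 = settings.initial_nodes
    # early attempts run under a reduced node cap so a stalled mesh fails
    # fast; the last attempt gets the full budget
    capped = min(settings.max_nodes, 30_000)
    attempts = [(n0, capped), (2 * n0 - 1, capped), (max(11, n0 // 4), settings.max_nodes)]
    history = []
    res = None
    for nodes, max_nodes in attempts:
        tgrid = np.linspace(0.0, T, nodes)
        res = solve_bvp(
            fun,
            bc,
            tgrid,
            guess(tgrid),
            tol=settings.tol,
            bc_tol=settings.bc_tol,
            max_nodes=max_nodes,
            verbose=settings.verbose,
        )
        history.append(
            {
                "initial_nodes": nodes,
                "status": int(res.status),
                "n_nodes": int(res.x.size),
                "max_rms_residual": float(np.max(res.rms_residuals))
                if res.rms_residuals.size
                else 0.0,
            }
        )
        if res.success:
            break
    diagnostics = {
        "status": int(res.status),
        "message": res.message,
        "n_nodes": int(res.x.size),
        "max_rms_residual": float(np.max(res.rms_residuals)) if res.rms_residuals.size else 0.0,
        "niter": int(res.niter),
        "attempts": history,
    }
    return res, diagnostics


def solve(problem: OCProblem, settings: SolverSettings | None = None) -> OCSolution:
    """Solve the coupled state--costate BVP with pointwise control elimination.

    Boundary conditions: ``x(0) = x0`` and transversality
    ``lambda(T) = M x(T)`` (which is ``lambda(T) = 0`` for ``M = 0``).
    """
    settings = settings or SolverSettings()
    _model.validate_model(problem.model).raise_if_invalid()
    model, cost = problem.model, problem.cost
    n = model.n
    x0, M = problem.x0, cost.M

    def fun(t, y):
        X, Lam = y[:n], y[n:]
        if cost.time_varying:
            dX = np.empty_like(X)
            dLam = np.empty_like(Lam)
            for col, tc in enumerate(t):
                U, _ = _stationary_batch(
                    problem, X[:, [col]], Lam[:, [col]], float(tc), settings
                )
                u = U[:, 0]
                dX[:, col] = _model.rhs(model, X[:, col], u)
                dLam[:, col] = adjoint_rhs(problem, X[:, col], u, Lam[:, col], float(tc))
            return np.vstack([dX, dLam])
        U, _ = _stationary_batch(problem, X, Lam, 0.0, settings)
        dX = _model.rhs(model, X, U)
        Q = cost.Q_at(0.0)
        lin = np.einsum("ijl,lk,jk->ik", model.C, U, Lam)
        quad = np.einsum("ijab,ak,bk,jk->ik", model.D, U, U, Lam)
        dLam = -Q @ X - model.A.T @ Lam - lin - quad
        return np.vstack([dX, dLam])

    def bc(ya, yb):
        return np.concatenate([ya[:n] - x0, yb[n:] - M @ yb[:n]])

    def guess(tgrid):
        return np.vstack(
            [np.tile(x0[:, None], (1, tgrid.size)), np.zeros((n, tgrid.size))]
        )

    res, diagnostics = _collocate_with_retries(
        fun, bc, cost.T, guess, settings
    )
    if not res.success and settings.raise_on_failure:
        raise ConvergenceError(
            f"BVP solver did not converge: {res.message}", diagnostics
        )
    t = res.x
    X, Lam = res.y[:n], res.y[n:]
    if cost.time_varying:
        U = np.empty((model.m, t.size))
        for col, tc in enumerate(t):
            Ucol, _ = _stationary_batch(
                problem, X[:, [col]], Lam[:, [col]], float(tc), settings
            )
            U[:, col] = Ucol[:, 0]
        resid = max(
            _projected_gradient_residual(
                problem, X[:, [c]], Lam[:, [c]], U[:, [c]], float(tc)
            )
            for c, tc in enumerate(t)
        )
    else:
        U, _ = _stationary_batch(problem, X, Lam, 0.0, settings)
        resid = _projected_gradient_residual(problem, X, Lam, U, 0.0)
    J = _quadratic_cost(problem, t, X.T, U.T)
    return OCSolution(
        t=t,
        x=X.T,
        lam=Lam.T,
        u=U.T,
        J=J,
        converged=bool(res.success),
        stationarity_residual=resid,
        bvp_diagnostics=diagnostics,
        problem=problem,
        _dense=res.sol,
    )


def _quadratic_cost(problem: OCProblem, t, x, u) -> float:
    """Trapezoid evaluation of the quadratic cost on a co-sampled grid."""
    cost = problem.cost
    if cost.time_varying:
        running = np.array(
            [
                x[i] @ cost.Q_at(ti) @ x[i] + u[i] @ cost.R_at(ti) @ u[i]
                for i, ti in enumerate(t)
            ]
        )
    else:
        Q, R = cost.Q_at(0.0), cost.R_at(0.0)
        running = np.einsum("ti,ij,tj->t", x, Q, x) + np.einsum(
            "tk,kl,tl->t", u, R, u
        )
    terminal = x[-1] @ cost.M @ x[-1]
    return float(0.5 * (terminal + np.trapezoid(running, t)))


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def _as_schedule(u_of_t, m: int):
    if callable(u_of_t):
        return u_of_t
    u_const = np.asarray(u_of_t, float).ravel()
    if u_const.shape != (m,):
        raise ModelValidationError(f"constant control must have length m={m}")
    return lambda t: u_const


def simulate_forward(
    model: ControlledODEModel,
    x0,
    u_of_t,
    T: float,
    *,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    check_nonnegative: bool = True,
) -> StateTrajectory:
    """Integrate the dynamics forward under a prescribed dosing schedule.

    ``u_of_t`` may be a callable ``t -> u``, a constant length-m vector, or an
    :class:`OCSolution` (replayed through its control interpolant).  Uses an
    adaptive stiff-capable integrator with tight tolerances.
    """
    if isinstance(u_of_t, OCSolution):
        u_of_t = u_of_t.control_interpolant()
    schedule = _as_schedule(u_of_t, model.m)
    x0 = np.asarray(x0, float).ravel()

    def f(t, x):
        return _model.rhs(model, x, np.asarray(schedule(t), float).ravel())

    res = solve_ivp(
        f,
        (0.0, T),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not res.success:
        raise ConvergenceError(
            f"forward integration failed at t={res.t[-1] if res.t.size else 0.0:g}: "
            f"{res.message}"
        )
    if check_nonnegative:
        _model.check_state_nonnegative(res.y)
    return StateTrajectory(t=res.t, x=res.y.T, sol=res.sol)
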