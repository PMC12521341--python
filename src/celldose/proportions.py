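"""Optimal control of cell-type *proportions* rather than absolute counts.

With total population ``N(t) = 1' x(t)`` and proportions ``r = x / N``, the
count dynamics (with ``B = 0``, i.e. negligible drug breakdown) induce closed
projective dynamics on the simplex:

    dr/dt = f(r, u) - (1' f(r, u)) r,
    f(r, u) = A r + sum_i r_i C_i u + sum_ij r_i (u' D^ij u) e_j,

where ``f`` is the count right-hand side evaluated at ``r`` (the quotient
rule applied to ``x / N`` gives ``dr/dt = dx/dt / N - (dN/dt / N) r``).
Summing the components gives ``1' dr/dt = (1' f)(1 - 1' r)``, so the simplex
``1' r = 1`` is invariant: proportions can be controlled without knowing the
population size.

The tracking cost penalises deviation from a target composition ``rtilde``:

    J = int_0^T [ (r - rtilde)' W_state (r - rtilde) + u' W_control u ] dt.

(W_state plays the role the count problem assigns to Q and W_control the role
of R; neutral names are used because the source formulation swaps the two
symbols.)  The Hamiltonian is again an exact quadratic in ``u``, so control
elimination reuses the box-QP machinery of the count solver, and the
first-order system in ``(r, lambda)`` is solved by the same collocation BVP
with ``r(0) = r0`` and ``lambda(T) = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import ControlledODEModel, ModelValidationError
from .solver import (
    ConvergenceError,
    OCSolution,
    SolverSettings,
    StateTrajectory,
    _box_qp_batch,
    _check_quadratic_form,
    _collocate_with_retries,
)

__all__ = [
    "ProportionProblem",
    "proportion_rhs",
    "proportion_hamiltonian",
    "proportion_adjoint_rhs",
    "proportion_optimality_gradient",
    "solve_proportion",
    "simulate_proportions",
]

_SIMPLEX_TOL = 1e-8


@dataclass
class ProportionProblem:
    """Target-tracking control problem on the proportion simplex."""

    model: ControlledODEModel
    target: np.ndarray
    W_state: np.ndarray
    W_control: np.ndarray
    T: float
    r0: np.ndarray
    control_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if np.any(self.model.B != 0):
            raise ModelValidationError(
                "proportion dynamics require B = 0 (no additive control)"
            )
        n, m = self.model.n, self.model.m
        self.target = np.asarray(self.target, float).ravel()
        self.r0 = np.asarray(self.r0, float).ravel()
        for name, r in (("target", self.target), ("r0", self.r0)):
            if r.shape != (n,):
                raise ModelValidationError(f"{name} must have length n={n}")
            if np.any(r < 0) or abs(r.sum() - 1.0) > _SIMPLEX_TOL:
                raise ModelValidationError(f"{name} must be a probability vector")
        self.W_state = _check_quadratic_form(
            "W_state", np.atleast_2d(self.W_state), definite=False, size=n
        )
        self.W_control = _check_quadratic_form(
            "W_control", np.atleast_2d(self.W_control), definite=True, size=m
        )
        if self.T <= 0:
            raise ModelValidationError("horizon T must be positive")
        if self.control_bounds is None:
            self.control_bounds = (np.zeros(m), np.ones(m))
        lb = np.broadcast_to(np.asarray(self.control_bounds[0], float), (m,)).copy()
        ub = np.broadcast_to(np.asarray(self.control_bounds[1], float), (m,)).copy()
        self.control_bounds = (lb, ub)


def _flux_batch(model: ControlledODEModel, Rm, U):
    """Normalised flux ``f(r, u)`` for column-stacked batches (n, k)."""
    return (
        model.A @ Rm
        + np.einsum("ik,ijl,lk->jk", Rm, model.C, U)
        + np.einsum("ik,ijab,ak,bk->jk", Rm, model.D, U, U)
    )


def proportion_rhs(problem: ProportionProblem, r, u) -> np.ndarray:
    """``dr/dt = f - (1'f) r``; sums to zero whenever ``1'r = 1``."""
    r = np.asarray(r, float)
    u = np.asarray(u, float)
    single = r.ndim == 1
    Rm = r[:, None] if single else r
    U = u[:, None] if single else u
    F = _flux_batch(problem.model, Rm, U)
    out = F - F.sum(axis=0, keepdims=True) * Rm
    return out[:, 0] if single else out


def proportion_hamiltonian(problem: ProportionProblem, r, u, lam) -> float:
    """Running tracking cost plus ``lambda . dr/dt`` (no 1/2 prefactor)."""
    r = np.asarray(r, float).ravel()
    u = np.asarray(u, float).ravel()
    lam = np.asarray(lam, float).ravel()
    dev = r - problem.target
    running = dev @ problem.W_state @ dev + u @ problem.W_control @ u
    return float(running + lam @ proportion_rhs(problem, r, u))


def _adjoint_batch(problem: ProportionProblem, Rm, U, Lam):
    model = problem.model
    n = model.n
    F = _flux_batch(model, Rm, U)
    onef = F.sum(axis=0)  # (k,)
    s = np.einsum("ik,ik->k", Lam, Rm)  # lambda'r per column
    # g_i = 1' df/dr_i ; h_i = lambda' df/dr_i
    ones = np.ones(n)
    cu = np.einsum("ijl,lk->ijk", model.C, U)  # (i, j, k): (C_i u)_j
    dq = np.einsum("ijab,ak,bk->ijk", model.D, U, U)  # u'D^ij u
    g = (model.A.T @ ones)[:, None] + cu.sum(axis=1) + dq.sum(axis=1)
    h = model.A.T @ Lam + np.einsum("ijk,jk->ik", cu, Lam) + np.einsum(
        "ijk,jk->ik", dq, Lam
    )
    Wsym = problem.W_state + problem.W_state.T
    dev = Rm - problem.target[:, None]
    return -(Wsym @ dev) - h + s[None, :] * g + onef[None, :] * Lam


def proportion_adjoint_rhs(problem: ProportionProblem, r, u, lam) -> np.ndarray:
    """``dlambda/dt = -dH/dr`` for the proportion Hamiltonian.

    Expanded form (component i):

        -[(W_s + W_s')(r - rtilde)]_i
        - lambda . df/dr_i + (lambda'r) * d(1'f)/dr_i + (1'f) lambda_i,

    with ``df/dr_i = A e_i + C_i u + sum_j (u'D^ij u) e_j``.  Verified against
    central finite differences of H in the test suite.
    """
    r = np.asarray(r, float).ravel()[:, None]
    u = np.asarray(u, float).ravel()[:, None]
    lam = np.asarray(lam, float).ravel()[:, None]
    return _adjoint_batch(problem, r, u, lam)[:, 0]


def _control_qp_batch(problem: ProportionProblem, Rm, Lam):
    """Hessian/gradient of H in u: ``dH/du = G u + b`` with

        G = 2 W_control + sum_ij r_i (lambda_j - lambda'r) (D^ij + D^ij'),
        b = sum_i r_i C_i' (lambda - (lambda'r) 1).
    """
    model = problem.model
    s = np.einsum("ik,ik->k", Lam, Rm)
    W = Lam - s[None, :]  # (n, k): lambda_j - (lambda'r)
    b = np.einsum("ik,ijl,jk->lk", Rm, model.C, W)
    Wc2 = problem.W_control + problem.W_control.T
    if model.has_interactions:
        Dsym = model.symmetrised_D()
        G = Wc2[:, :, None] + np.einsum("ik,jk,ijab->abk", Rm, W, Dsym)
    else:
        G = Wc2
    return G, b


def proportion_optimality_gradient(problem: ProportionProblem, r, u, lam) -> np.ndarray:
    """``dH/du`` at a point; zero (projected) at the optimal control."""
    r = np.asarray(r, float).ravel()[:, None]
    u = np.asarray(u, float).ravel()
    lam = np.asarray(lam, float).ravel()[:, None]
    G, b = _control_qp_batch(problem, r, lam)
    Gmat = G if G.ndim == 2 else G[:, :, 0]
    return Gmat @ u + b[:, 0]


def _eliminate_control(problem: ProportionProblem, Rm, Lam, settings: SolverSettings):
    G, b = _control_qp_batch(problem, Rm, Lam)
    lb, ub = problem.control_bounds
    return _box_qp_batch(G, b, lb, ub, settings)


def solve_proportion(
    problem: ProportionProblem, settings: SolverSettings | None = None
) -> OCSolution:
    """Collocation solve of the proportion BVP: ``r(0) = r0``,
    ``lambda(T) = 0``, control eliminated pointwise on the box."""
    settings = settings or SolverSettings()
    n = problem.model.n

    def fun(t, y):
        Rm, Lam = y[:n], y[n:]
        U, _ = _eliminate_control(problem, Rm, Lam, settings)
        dR = proportion_rhs(problem, Rm, U)
        dLam = _adjoint_batch(problem, Rm, U, Lam)
        return np.vstack([dR, dLam])

    def bc(ya, yb):
        return np.concatenate([ya[:n] - problem.r0, yb[n:]])

    def guess(tgrid):
        return np.vstack(
            [np.tile(problem.r0[:, None], (1, tgrid.size)), np.zeros((n, tgrid.size))]
        )

    res, diagnostics = _collocate_with_retries(fun, bc, problem.T, guess, settings)
    if not res.success and settings.raise_on_failure:
        raise ConvergenceError(f"proportion BVP did not converge: {res.message}", diagnostics)
    t = res.x
    Rm, Lam = res.y[:n], res.y[n:]
    U, _ = _eliminate_control(problem, Rm, Lam, settings)
    dev = Rm - problem.target[:, None]
    running = np.einsum("ik,ij,jk->k", dev, problem.W_state, dev) + np.einsum(
        "ak,ab,bk->k", U, problem.W_control, U
    )
    J = float(np.trapezoid(running, t))
    G, b = _control_qp_batch(problem, Rm, Lam)
    grad = (G @ U if G.ndim == 2 else np.einsum("abk,bk->ak", G, U)) + b
    lb, ub = problem.control_bounds
    proj = np.clip(U - grad, lb[:, None], ub[:, None])
    resid = float(np.abs(U - proj).max(initial=0.0))
    return OCSolution(
        t=t,
        x=Rm.T,
        lam=Lam.T,
        u=U.T,
        J=J,
        converged=bool(res.success),
        stationarity_residual=resid,
        bvp_diagnostics=diagnostics,
        problem=None,
        _dense=res.sol,
    )


def simulate_proportions(
    problem: ProportionProblem,
    r0,
    u_of_t,
    T: float | None = None,
    *,
    t_eval=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Integrate the proportion dynamics forward under a fixed schedule."""
    if T is None:
        T = problem.T
    if callable(u_of_t):
        schedule = u_of_t
    else:
        u_const = np.asarray(u_of_t, float).ravel()
        schedule = lambda t: u_const  # noqa: E731
    r0 = np.asarray(r0, float).ravel()

    def f(t, r):
        return proportion_rhs(problem, r, np.asarray(schedule(t), float).ravel())

    res = solve_ivp(
        f, (0.0, T), r0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=True,
    )
    if not res.success:
        raise ConvergenceError(f"proportion integration failed: {res.message}")
    return StateTrajectory(t=res.t, x=res.y.T, sol=res.sol)
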