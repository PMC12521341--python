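"""Cost-functional evaluation and treatment-comparison statistics.

The headline comparison asks whether a time-varying optimal schedule beats
"the same amount of drug given flat": for each drug the optimal trace is
averaged over the horizon,

    ubar_k = (1/T) int_0^T u_k(tau) dtau,

the state is re-simulated under the constant schedule ``u = ubar``, and the
efficacy ratio

    eta = sum_i xbar_i(T) / sum_i x_i(T)

compares final total cell counts (constant over optimal).  ``eta > 1`` means
the optimal schedule ends with fewer cells than constant dosing at the same
average exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComparisonResult",
    "cost_functional",
    "mean_control",
    "integrated_drug_cost",
    "efficacy_ratio",
    "resample_uniform",
]

#: uniform grid size used to decouple time averages from the adaptive mesh
RESAMPLE_POINTS = 2001


@dataclass
class ComparisonResult:
    """Optimal-vs-constant comparison bundle (one problem instance)."""

    eta: float
    ubar: np.ndarray
    J_optimal: float
    J_constant: float
    drug_cost_optimal: float
    drug_cost_constant: float
    final_counts_optimal: np.ndarray
    final_counts_constant: np.ndarray

    def summary(self) -> dict:
        return {
            "eta": self.eta,
            **{f"ubar_{k + 1}": float(v) for k, v in enumerate(self.ubar)},
            "J_optimal": self.J_optimal,
            "J_constant": self.J_constant,
            "drug_cost_optimal": self.drug_cost_optimal,
            "drug_cost_constant": self.drug_cost_constant,
            "final_total_optimal": float(np.sum(self.final_counts_optimal)),
            "final_total_constant": float(np.sum(self.final_counts_constant)),
        }


def _co_sampled(t, *arrays):
    t = np.asarray(t, float).ravel()
    out = []
    for a in arrays:
        a = np.asarray(a, float)
        if a.ndim == 1:
            a = a[:, None]
        if a.shape[0] != t.size:
            raise ValueError(
                f"trajectory with {a.shape[0]} rows not co-sampled with grid of {t.size}"
            )
        out.append(a)
    return (t, *out)


def resample_uniform(t, y, npoints: int = RESAMPLE_POINTS):
    """Linear resampling of a trajectory onto a uniform grid over [t0, tN]."""
    t, y = _co_sampled(t, y)[:2]
    tu = np.linspace(t[0], t[-1], npoints)
    yu = np.column_stack([np.interp(tu, t, y[:, j]) for j in range(y.shape[1])])
    return tu, yu


def cost_functional(problem, t, x, u) -> float:
    """``J = 1/2 [x(T)'Mx(T) + int (x'Qx + u'Ru) dt]`` by trapezoid quadrature."""
    from .solver import _quadratic_cost

    t, x, u = _co_sampled(t, x, u)
    return _quadratic_cost(problem, t, x, u)


def mean_control(t, u, T: float | None = None) -> np.ndarray:
    """Per-drug time average ``(1/T) int_0^T u_k dtau`` (trapezoid)."""
    t, u = _co_sampled(t, u)
    if t.size < 2:
        raise ValueError("control trajectory must have at least two samples")
    if T is None:
        T = float(t[-1] - t[0])
    if T <= 0:
        raise ValueError("horizon T must be positive")
    return np.trapezoid(u, t, axis=0) / T


def integrated_drug_cost(t, u, R) -> float:
    """Integrated control penalty ``int u'Ru dtau`` (trapezoid)."""
    t, u = _co_sampled(t, u)
    R = np.atleast_2d(np.asarray(R, float))
    if R.shape != (u.shape[1], u.shape[1]):
        raise ValueError(f"R must be {u.shape[1]}x{u.shape[1]}, got {R.shape}")
    running = np.einsum("tk,kl,tl->t", u, R, u)
    return float(np.trapezoid(running, t))


def efficacy_ratio(problem, optimal, npoints: int = RESAMPLE_POINTS) -> ComparisonResult:
    """Compare a converged optimal solution with its constant-mean comparator.

    The comparator only re-simulates the state under ``u = ubar``; it does not
    re-solve an optimal control problem.  Time averages are taken on a uniform
    resampling of the solver mesh so that adaptive node placement does not
    bias the average.
    """
    from .solver import simulate_forward

    tu, uu = resample_uniform(optimal.t, optimal.u, npoints)
    ubar = mean_control(tu, uu)
    T = float(problem.cost.T)
    traj = simulate_forward(problem.model, problem.x0, ubar, T)
    final_opt = np.asarray(optimal.x[-1], float)
    final_const = traj.final_state
    total_opt = float(np.sum(final_opt))
    if total_opt <= 0:
        raise ValueError("optimal final total count is not positive; eta undefined")
    eta = float(np.sum(final_const) / total_opt)
    R = problem.cost.R_at(0.0)
    tc, xc = traj.t, traj.x
    uc = np.tile(ubar, (tc.size, 1))
    return ComparisonResult(
        eta=eta,
        ubar=ubar,
        J_optimal=float(optimal.J),
        J_constant=cost_functional(problem, tc, xc, uc),
        drug_cost_optimal=integrated_drug_cost(tu, uu, R),
        drug_cost_constant=integrated_drug_cost(tc, uc, R),
        final_counts_optimal=final_opt,
        final_counts_constant=final_const,
    )
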