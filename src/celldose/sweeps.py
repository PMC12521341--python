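"""Parameter-space analyses: efficacy maps, toxicity splits, marginal costs,
drug-sensitivity variance partition and dosing-noise robustness.

Every sweep runs one optimal-control solve per grid cell, records per-cell
convergence, and continues past failed cells (failures carry NaN).  All
randomness (the Monte-Carlo robustness study) flows from a single integer
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .model import ModelValidationError
from .presets import (
    NB_DRUGS,
    NeuroblastomaReducedParams,
    ToxicitySweepSpec,
    TwoPopulationParams,
    build_two_population,
    default_problem,
    reduce_neuroblastoma,
)
from .solver import (
    ConvergenceError,
    CostSpec,
    OCProblem,
    OCSolution,
    SingularOptimality,
    SolverSettings,
    simulate_forward,
    solve,
)

__all__ = [
    "SweepResult",
    "MarginalCostResult",
    "SensitivityPartition",
    "RobustnessResult",
    "efficacy_sweep",
    "toxicity_split_sweep",
    "marginal_max_cost",
    "sensitivity_partition",
    "noise_robustness",
    "motif_regime_traces",
]

_SOLVE_ERRORS = (ConvergenceError, SingularOptimality, ModelValidationError)


@dataclass
class SweepResult:
    """Gridded sweep output; ``failures`` flags cells whose solve failed."""

    axes: dict[str, np.ndarray]
    eta_grid: np.ndarray
    drug_cost_grid: np.ndarray
    per_drug_cost_grids: dict[str, np.ndarray]
    failures: np.ndarray
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per grid cell per metric."""
        names = list(self.axes)
        grids = np.meshgrid(*self.axes.values(), indexing="ij")
        rows = {name: g.ravel() for name, g in zip(names, grids)}
        metric_grids = {
            "eta": self.eta_grid,
            "drug_cost": self.drug_cost_grid,
            **{f"drug_cost_{k}": v for k, v in self.per_drug_cost_grids.items()},
            **self.extra,
        }
        frames = []
        for metric, grid in metric_grids.items():
            df = pd.DataFrame(rows)
            df["metric"] = metric
            df["value"] = np.asarray(grid, float).ravel()
            df["failed"] = self.failures.ravel()
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _solve_two_population(alpha, beta, R, T, x0, settings) -> tuple[OCProblem, OCSolution]:
    model = build_two_population(TwoPopulationParams(alpha=alpha, beta=beta))
    cost = CostSpec(M=np.zeros((2, 2)), Q=np.eye(2), R=R, T=T)
    problem = OCProblem(model=model, cost=cost, x0=x0)
    return problem, solve(problem, settings)


def efficacy_sweep(
    alphas,
    betas,
    *,
    R=None,
    T: float = 7.0,
    x0=(1.0, 1.0),
    settings: SolverSettings | None = None,
) -> SweepResult:
    """Efficacy ratio eta and integrated drug cost over an (alpha, beta) grid.

    Per cell: solve the two-population problem (Q = I, R = 0.1 I unless
    overridden), form the constant-mean comparator and record eta together
    with the total and per-drug integrated control penalties.
    """
    alphas = np.atleast_1d(np.asarray(alphas, float))
    betas = np.atleast_1d(np.asarray(betas, float))
    if np.any(alphas <= 0) or np.any(betas <= 0):
        raise ModelValidationError("alpha and beta grids must be positive")
    R = 0.1 * np.eye(2) if R is None else np.atleast_2d(R)
    shape = (alphas.size, betas.size)
    eta = np.full(shape, np.nan)
    cost_grid = np.full(shape, np.nan)
    per_drug = {d: np.full(shape, np.nan) for d in ("u_c", "u_p")}
    failed = np.zeros(shape, dtype=bool)
    for (i, a), (j, b) in itertools.product(enumerate(alphas), enumerate(betas)):
        try:
            problem, sol = _solve_two_population(a, b, R, T, np.asarray(x0), settings)
            comp = _metrics.efficacy_ratio(problem, sol)
        except _SOLVE_ERRORS:
            failed[i, j] = True
            continue
        eta[i, j] = comp.eta
        cost_grid[i, j] = comp.drug_cost_optimal
        tu, uu = _metrics.resample_uniform(sol.t, sol.u)
        for k, d in enumerate(("u_c", "u_p")):
            per_drug[d][i, j] = integrate_single_drug_cost(tu, uu[:, k], R[k, k])
    return SweepResult(
        axes={"alpha": alphas, "beta": betas},
        eta_grid=eta,
        drug_cost_grid=cost_grid,
        per_drug_cost_grids=per_drug,
        failures=failed,
    )


def integrate_single_drug_cost(t, u_k, r_kk: float) -> float:
    """Per-drug share ``int r_kk u_k^2 dtau`` of the integrated penalty."""
    u_k = np.asarray(u_k, float).ravel()
    return float(np.trapezoid(r_kk * u_k**2, t))


def toxicity_split_sweep(
    spec: ToxicitySweepSpec,
    R_alpha_grid,
    phi_grid,
    *,
    T: float = 7.0,
    x0=(1.0, 1.0),
    settings: SolverSettings | None = None,
) -> SweepResult:
    """Efficacy along the (alpha, beta) path as the penalty split is varied.

    Per cell: set ``(alpha, beta)`` from the path at ``phi``, set
    ``R = diag(R_alpha, R0 - R_alpha)`` and record eta and drug costs.
    """
    R_alpha_grid = np.atleast_1d(np.asarray(R_alpha_grid, float))
    phi_grid = np.atleast_1d(np.asarray(phi_grid, float))
    shape = (R_alpha_grid.size, phi_grid.size)
    eta = np.full(shape, np.nan)
    cost_grid = np.full(shape, np.nan)
    per_drug = {d: np.full(shape, np.nan) for d in ("u_c", "u_p")}
    failed = np.zeros(shape, dtype=bool)
    for (i, ra), (j, phi) in itertools.product(
        enumerate(R_alpha_grid), enumerate(phi_grid)
    ):
        try:
            alpha, beta = spec.path(phi)
            R = spec.penalty(ra)
            problem, sol = _solve_two_population(alpha, beta, R, T, np.asarray(x0), settings)
            comp = _metrics.efficacy_ratio(problem, sol)
        except _SOLVE_ERRORS:
            failed[i, j] = True
            continue
        eta[i, j] = comp.eta
        cost_grid[i, j] = comp.drug_cost_optimal
        tu, uu = _metrics.resample_uniform(sol.t, sol.u)
        for k, d in enumerate(("u_c", "u_p")):
            per_drug[d][i, j] = integrate_single_drug_cost(tu, uu[:, k], R[k, k])
    return SweepResult(
        axes={"R_alpha": R_alpha_grid, "phi": phi_grid},
        eta_grid=eta,
        drug_cost_grid=cost_grid,
        per_drug_cost_grids=per_drug,
        failures=failed,
    )


def _solve_neuroblastoma(lam, delta, delta_apop, settings) -> tuple[OCProblem, OCSolution]:
    model = reduce_neuroblastoma(
        NeuroblastomaReducedParams(lam=lam, delta=delta, delta_apop=delta_apop)
    )
    problem = default_problem(model, "neuroblastoma")
    return problem, solve(problem, settings)


@dataclass
class MarginalCostResult:
    """Maximum marginal drug cost ``c(zeta, xi) = max_rho ctilde(zeta, xi, rho)``.

    ``ctilde_grid`` holds the raw optimal-control cost J on the full
    (lam, delta, delta_apop) grid; ``pair_grids[(zeta, xi)]`` maximises over
    the remaining parameter and ``traces[name]`` over the remaining two.
    """

    axes: dict[str, np.ndarray]
    ctilde_grid: np.ndarray
    pair_grids: dict[tuple[str, str], np.ndarray]
    traces: dict[str, np.ndarray]
    failures: np.ndarray


_NB_PARAM_NAMES = ("lam", "delta", "delta_apop")


def marginal_max_cost(
    lam_grid,
    delta_grid,
    delta_apop_grid,
    *,
    settings: SolverSettings | None = None,
) -> MarginalCostResult:
    """Grid the optimal cost over (lam, delta, delta_apop) and marginalise.

    For each ordered parameter pair the reported cost is the maximum of the
    converged costs over the third parameter's grid (NaN where every value of
    the marginalised parameter failed).
    """
    axes = {
        "lam": np.atleast_1d(np.asarray(lam_grid, float)),
        "delta": np.atleast_1d(np.asarray(delta_grid, float)),
        "delta_apop": np.atleast_1d(np.asarray(delta_apop_grid, float)),
    }
    shape = tuple(v.size for v in axes.values())
    ctilde = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    for (i, lam), (j, d), (k, da) in itertools.product(
        *(enumerate(v) for v in axes.values())
    ):
        try:
            _, sol = _solve_neuroblastoma(lam, d, da, settings)
            ctilde[i, j, k] = sol.J
        except _SOLVE_ERRORS:
            failed[i, j, k] = True
    pair_grids = {}
    names = _NB_PARAM_NAMES
    with np.errstate(all="ignore"):
        for za, xa in itertools.permutations(range(3), 2):
            rho = ({0, 1, 2} - {za, xa}).pop()
            grid = np.nanmax(np.moveaxis(ctilde, (za, xa, rho), (0, 1, 2)), axis=2)
            pair_grids[(names[za], names[xa])] = grid
        traces = {
            names[a]: np.nanmax(
                np.moveaxis(ctilde, a, 0).reshape(shape[a], -1), axis=1
            )
            for a in range(3)
        }
    return MarginalCostResult(
        axes=axes,
        ctilde_grid=ctilde,
        pair_grids=pair_grids,
        traces=traces,
        failures=failed,
    )


@dataclass
class SensitivityPartition:
    """Per-drug variance of the mean dose as delta varies, per (lam,
    delta_apop) cell, and the index/name of the most delta-sensitive drug."""

    lam_grid: np.ndarray
    delta_apop_grid: np.ndarray
    delta_grid: np.ndarray
    v_grids: np.ndarray  # (m, n_lam, n_apop)
    argmax_grid: np.ndarray  # (n_lam, n_apop) drug index, -1 where failed
    drug_labels: tuple[str, ...]
    failures: np.ndarray

    def most_sensitive(self, i: int, j: int) -> str:
        idx = int(self.argmax_grid[i, j])
        return "<failed>" if idx < 0 else self.drug_labels[idx]


def sensitivity_partition(
    lam_grid,
    delta_apop_grid,
    delta_grid,
    *,
    settings: SolverSettings | None = None,
) -> SensitivityPartition:
    """Partition (lam, delta_apop) space by the drug whose mean dose is most
    sensitive to the interconversion-effect rate delta.

    Per cell: solve the reduced neuroblastoma problem at every delta in the
    grid, take each drug's horizon-mean dose, and record the variance across
    delta.  Ties pick the first drug in the fixed ordering
    (u_RA, u_chemo, u_trk, u_NGF).
    """
    lam_grid = np.atleast_1d(np.asarray(lam_grid, float))
    delta_apop_grid = np.atleast_1d(np.asarray(delta_apop_grid, float))
    delta_grid = np.atleast_1d(np.asarray(delta_grid, float))
    m = len(NB_DRUGS)
    shape = (lam_grid.size, delta_apop_grid.size)
    v = np.full((m,) + shape, np.nan)
    arg = np.full(shape, -1, dtype=int)
    failed = np.zeros(shape, dtype=bool)
    for (i, lam), (j, da) in itertools.product(
        enumerate(lam_grid), enumerate(delta_apop_grid)
    ):
        means = []
        for d in delta_grid:
            try:
                _, sol = _solve_neuroblastoma(lam, d, da, settings)
            except _SOLVE_ERRORS:
                continue
            tu, uu = _metrics.resample_uniform(sol.t, sol.u)
            means.append(_metrics.mean_control(tu, uu))
        if not means:
            failed[i, j] = True
            continue
        means = np.asarray(means)  # (n_delta_ok, m)
        variances = means.var(axis=0)
        v[:, i, j] = variances
        arg[i, j] = int(np.argmax(variances))
    return SensitivityPartition(
        lam_grid=lam_grid,
        delta_apop_grid=delta_apop_grid,
        delta_grid=delta_grid,
        v_grids=v,
        argmax_grid=arg,
        drug_labels=NB_DRUGS,
        failures=failed,
    )


@dataclass
class RobustnessResult:
    """Monte-Carlo dosing-noise study output (fully seeded)."""

    noise_amplitudes: np.ndarray
    final_totals: np.ndarray  # (n_amplitudes, replicates)
    cost_deltas: np.ndarray  # (n_amplitudes, replicates)
    max_relative_final_count_deviation: np.ndarray  # (n_amplitudes,)
    baseline_final_total: float
    seed: int
    failures: np.ndarray

    @property
    def worst_deviation(self) -> float:
        return float(np.nanmax(self.max_relative_final_count_deviation))


def _ou_path(rng, t, sigma: float, corr_time: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample on grid ``t`` (exact update)."""
    eps = np.empty(t.size)
    eps[0] = sigma * rng.standard_normal()
    phi = np.exp(-np.diff(t) / corr_time)
    innov = sigma * np.sqrt(1.0 - phi**2)
    shocks = rng.standard_normal(t.size - 1)
    for i in range(t.size - 1):
        eps[i + 1] = phi[i] * eps[i] + innov[i] * shocks[i]
    return eps


def noise_robustness(
    problem: OCProblem,
    optimal: OCSolution,
    amplitudes,
    replicates: int = 200,
    seed: int = 0,
    *,
    corr_time: float = 1.0,
    grid_points: int = 701,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> RobustnessResult:
    """Perturb the optimal dosing traces with temporally-correlated noise.

    Each drug trace receives an independent stationary Ornstein-Uhlenbeck
    perturbation (standard deviation = amplitude, correlation time
    ``corr_time`` in rescaled units), is clipped back to the admissible box,
    and the state ODEs are re-simulated.  Recorded per replicate: the final
    total cell count and the cost difference against the unperturbed optimum.
    The baseline uses the same resampled schedule, so zero amplitude gives
    exactly zero deviation.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if np.any(amplitudes < 0):
        raise ValueError("noise amplitudes must be >= 0")
    T = float(problem.cost.T)
    tgrid, ugrid = _metrics.resample_uniform(optimal.t, optimal.u, grid_points)
    lb, ub = problem.control_bounds
    m = problem.model.m

    def schedule_from(utable):
        def u_of_t(s):
            return np.array([np.interp(s, tgrid, utable[:, k]) for k in range(m)])

        return u_of_t

    base_traj = simulate_forward(
        problem.model, problem.x0, schedule_from(ugrid), T, t_eval=tgrid,
        rtol=rtol, atol=atol, check_nonnegative=False,
    )
    base_total = float(base_traj.final_state.sum())
    J_base = _metrics.cost_functional(problem, base_traj.t, base_traj.x, ugrid)
    rng = np.random.default_rng(seed)
    shape = (amplitudes.size, replicates)
    totals = np.full(shape, np.nan)
    deltas = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    for a, sigma in enumerate(amplitudes):
        for r in range(replicates):
            noise = np.column_stack(
                [_ou_path(rng, tgrid, sigma, corr_time) for _ in range(m)]
            )
            upert = np.clip(ugrid + noise, lb, ub)
            try:
                traj = simulate_forward(
                    problem.model, problem.x0, schedule_from(upert), T,
                    t_eval=tgrid, rtol=rtol, atol=atol, check_nonnegative=False,
                )
            except ConvergenceError:
                failed[a, r] = True
                continue
            totals[a, r] = traj.final_state.sum()
            deltas[a, r] = (
                _metrics.cost_functional(problem, traj.t, traj.x, upert) - J_base
            )
    with np.errstate(invalid="ignore"):
        max_dev = np.nanmax(np.abs(totals - base_total) / base_total, axis=1)
    return RobustnessResult(
        noise_amplitudes=amplitudes,
        final_totals=totals,
        cost_deltas=deltas,
        max_relative_final_count_deviation=max_dev,
        baseline_final_total=base_total,
        seed=int(seed),
        failures=failed,
    )


#: the two motif regimes: (delta_apop, lam) with delta varied in each
MOTIF_REGIMES = {
    "RA_sensitive": {"delta_apop": 0.3, "lam": 0.2},
    "chemo_sensitive": {"delta_apop": 0.3, "lam": 0.4},
}
MOTIF_DELTAS = (0.05, 0.25, 0.45)


def motif_regime_traces(
    *, deltas=MOTIF_DELTAS, settings: SolverSettings | None = None
) -> pd.DataFrame:
    """Optimal dosing traces for the two qualitative regimes.

    Motif classification is descriptive: the traces for the RA-sensitive
    (lam = 0.2) and chemotherapy-sensitive (lam = 0.4) regimes at
    delta_apop = 0.3 are emitted for inspection; no automated shape
    classifier is applied.
    """
    frames = []
    for regime, pars in MOTIF_REGIMES.items():
        for d in deltas:
            _, sol = _solve_neuroblastoma(pars["lam"], d, pars["delta_apop"], settings)
            df = sol.to_frame()
            df["regime"] = regime
            df["delta"] = d
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
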