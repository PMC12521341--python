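"""Semi-linear controlled ODE models with multiplicative drug action.

The state ``x`` collects cell counts of ``n`` interconverting sub-populations
and the control ``u`` collects the effective pharmacodynamic action of ``m``
drugs, each constrained to ``[0, 1]``.  The dynamics are

    dx/dt = A x + B u + L(u, x) + N(u, x),

where ``A`` holds growth and spontaneous interconversion rates, ``B`` holds
additive (drug-breakdown) terms, ``L`` collects every monomial ``u_l * x_i``
(single-drug action on a population) and ``N`` collects every pairwise drug
synergy ``x_i * u_k * u_l`` with ``k != l``.  Coefficients are stored as

* ``C[i]`` — an ``n x m`` matrix whose entry ``(j, l)`` is the coefficient of
  ``u_l * x_i`` in the equation for ``x_j``;
* ``D[i][j]`` — an ``m x m`` strictly lower-triangular matrix whose entry
  ``(k, l)`` is the coefficient of ``x_i * u_k * u_l`` in the equation for
  ``x_j``.  The strict triangularity encodes the symmetry of pairwise
  interactions (one canonical entry per unordered drug pair) and excludes
  quadratic self-action ``u_k**2``, which is not a synergy.

All quantities are dimensionless: time is rescaled by a reference rate ``k``
(``tau = k t``) and every coefficient matrix is divided by ``k``.  The
:func:`ControlledODEModel.rescaled` helper performs this rescaling for models
assembled from raw rates and records the scale factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlledODEModel",
    "ModelValidationError",
    "ValidationReport",
    "fold_interaction_matrix",
    "linear_control_term",
    "interaction_term",
    "rhs",
    "validate_model",
    "check_state_nonnegative",
]

#: states more negative than this raise; in (-tol, 0) they only warn
NEGATIVITY_TOLERANCE = 1e-8


class ModelValidationError(ValueError):
    """Raised when a model's coefficient structure is inconsistent."""


@dataclass
class ValidationReport:
    """Outcome of structural validation; ``violations`` is empty when valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if self.violations:
            raise ModelValidationError("; ".join(self.violations))


def fold_interaction_matrix(full: np.ndarray, name: str = "D") -> np.ndarray:
    """Fold a full pairwise-interaction specification into canonical form.

    The canonical storage is strictly lower triangular: the coefficients of
    ``u_k u_l`` and ``u_l u_k`` (the same monomial) are summed into the single
    entry ``(max(k,l), min(k,l))``.  Any diagonal content (a ``u_k**2`` term)
    is rejected — quadratic self-action is excluded from the model class.
    """
    full = np.asarray(full, dtype=float)
    if full.ndim != 2 or full.shape[0] != full.shape[1]:
        raise ModelValidationError(f"{name} must be square, got shape {full.shape}")
    diag = np.diag(full)
    if np.any(diag != 0.0):
        k = int(np.nonzero(diag)[0][0])
        raise ModelValidationError(
            f"{name} has nonzero diagonal entry at drug index {k}: "
            "quadratic self-action u_k^2 is not an interaction term"
        )
    return np.tril(full, -1) + np.triu(full, 1).T


@dataclass
class ControlledODEModel:
    """Structured coefficient set (A, B, {C_i}, {D^ij}) for the dynamics above.

    Parameters
    ----------
    A : (n, n) array
        Growth / spontaneous interconversion matrix (per unit rescaled time).
    B : (n, m) array
        Additive control matrix (zero in all worked examples here).
    C : (n, n, m) array
        ``C[i]`` is the n x m single-drug coefficient matrix for state ``i``.
    D : (n, n, m, m) array
        ``D[i, j]`` is the strictly lower-triangular m x m synergy matrix for
        source state ``i`` feeding equation ``j``.
    state_labels, drug_labels : optional name lists.
    time_scale : float
        Reference rate used to non-dimensionalise time (recorded only).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: tuple[str, ...] | None = None
    drug_labels: tuple[str, ...] | None = None
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n = self.A.shape[0]
        self.B = np.asarray(self.B, dtype=float).reshape(n, -1)
        m = self.B.shape[1]
        self.C = np.asarray(self.C, dtype=float).reshape(n, n, m)
        self.D = np.asarray(self.D, dtype=float).reshape(n, n, m, m)
        if self.state_labels is not None:
            self.state_labels = tuple(self.state_labels)
        if self.drug_labels is not None:
            self.drug_labels = tuple(self.drug_labels)
        validate_model(self).raise_if_invalid()

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_terms(
        cls,
        A,
        B=None,
        C=None,
        D=None,
        *,
        n: int | None = None,
        m: int | None = None,
        state_labels=None,
        drug_labels=None,
        fold_D: bool = False,
        time_scale: float = 1.0,
    ) -> "ControlledODEModel":
        """Assemble a model from (possibly sparse) term specifications.

        ``C`` may be a sequence of ``n`` matrices or a dict ``{i: matrix}``;
        ``D`` a dict ``{(i, j): matrix}`` or full nested sequence.  With
        ``fold_D=True`` full symmetric interaction matrices are folded into
        the canonical strictly-lower storage (diagonal content errors).
        """
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if n is None:
            n = A.shape[0]
        if B is None:
            if m is None:
                raise ModelValidationError("drug count m required when B is omitted")
            B = np.zeros((n, m))
        B = np.asarray(B, dtype=float).reshape(n, -1)
        if m is None:
            m = B.shape[1]
        Carr = np.zeros((n, n, m))
        if C is not None:
            if not isinstance(C, dict) and len(C) != n:
                raise ModelValidationError(
                    f"C must provide one n x m matrix per state: got {len(C)}, expected {n}"
                )
            items = C.items() if isinstance(C, dict) else enumerate(C)
            for i, Ci in items:
                if not 0 <= i < n:
                    raise ModelValidationError(f"C index {i} out of range for n={n}")
                Carr[i] = np.asarray(Ci, dtype=float)
        Darr = np.zeros((n, n, m, m))
        if D is not None:
            if isinstance(D, dict):
                items = D.items()
            else:
                items = (
                    ((i, j), np.asarray(D)[i, j]) for i in range(n) for j in range(n)
                )
            for (i, j), Dij in items:
                Dij = np.asarray(Dij, dtype=float)
                if fold_D:
                    Dij = fold_interaction_matrix(Dij, name=f"D^({i},{j})")
                Darr[i, j] = Dij
        return cls(
            A,
            B,
            Carr,
            Darr,
            state_labels=state_labels,
            drug_labels=drug_labels,
            time_scale=time_scale,
        )

    # -- basic properties -----------------------------------------------

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]

    @property
    def has_interactions(self) -> bool:
        return bool(np.any(self.D))

    def rescaled(self, k: float) -> "ControlledODEModel":
        """Return the model in rescaled time ``tau = k t`` (divide rates by k)."""
        if k <= 0:
            raise ModelValidationError("time scale must be positive")
        return ControlledODEModel(
            self.A / k,
            self.B / k,
            self.C / k,
            self.D / k,
            state_labels=self.state_labels,
            drug_labels=self.drug_labels,
            time_scale=self.time_scale * k,
        )

    def symmetrised_D(self) -> np.ndarray:
        """Full symmetric form ``D + D^T`` per (i, j) pair.

        This is the Hessian contribution of each synergy block: the quadratic
        form ``u^T D u`` has gradient ``(D + D^T) u``.
        """
        return self.D + np.swapaxes(self.D, -1, -2)

    # -- dynamics --------------------------------------------------------

    def linear_control_term(self, x, u) -> np.ndarray:
        return linear_control_term(self, x, u)

    def interaction_term(self, x, u) -> np.ndarray:
        return interaction_term(self, x, u)

    def rhs(self, x, u) -> np.ndarray:
        return rhs(self, x, u)


# ---------------------------------------------------------------------------
# batch-aware evaluation (x, u may be (n,)/(m,) vectors or (n,k)/(m,k) stacks)
# ---------------------------------------------------------------------------


def _check_dims(model: ControlledODEModel, x, u):
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape[0] != model.n:
        raise ModelValidationError(
            f"state has leading dimension {x.shape[0]}, expected n={model.n}"
        )
    if u.shape[0] != model.m:
        raise ModelValidationError(
            f"control has leading dimension {u.shape[0]}, expected m={model.m}"
        )
    return x, u


def linear_control_term(model: ControlledODEModel, x, u) -> np.ndarray:
    """Single-drug multiplicative term ``L(u, x)``; component j is
    ``sum_{i,l} C[i][j,l] u_l x_i``."""
    x, u = _check_dims(model, x, u)
    if x.ndim == 1:
        # sum_i x_i (C_i @ u)
        return np.einsum("i,ijl,l->j", x, model.C, u)
    return np.einsum("ik,ijl,lk->jk", x, model.C, u)


def interaction_term(model: ControlledODEModel, x, u) -> np.ndarray:
    """Pairwise synergy term ``N(u, x)``; component j is
    ``sum_i x_i u^T D[i,j] u`` (strictly lower entries only)."""
    x, u = _check_dims(model, x, u)
    if x.ndim == 1:
        return np.einsum("i,ijkl,k,l->j", x, model.D, u, u)
    return np.einsum("ik,ijab,ak,bk->jk", x, model.D, u, u)


def rhs(model: ControlledODEModel, x, u) -> np.ndarray:
    """Full right-hand side ``A x + B u + L(u, x) + N(u, x)``."""
    x, u = _check_dims(model, x, u)
    return (
        model.A @ x
        + model.B @ u
        + linear_control_term(model, x, u)
        + interaction_term(model, x, u)
    )


def validate_model(model: ControlledODEModel) -> ValidationReport:
    """Check dimensional consistency and canonical synergy storage."""
    report = ValidationReport()
    A, B, C, D = model.A, model.B, model.C, model.D
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        report.violations.append(f"A must be square, got {A.shape}")
        return report
    n = A.shape[0]
    m = B.shape[1] if B.ndim == 2 else -1
    if B.ndim != 2 or B.shape[0] != n:
        report.violations.append(f"B must be n x m with n={n}, got {B.shape}")
    if C.shape != (n, n, m):
        report.violations.append(f"C must have shape (n, n, m)={(n, n, m)}, got {C.shape}")
    if D.shape != (n, n, m, m):
        report.violations.append(
            f"D must have shape (n, n, m, m)={(n, n, m, m)}, got {D.shape}"
        )
    else:
        for i in range(n):
            for j in range(n):
                Dij = D[i, j]
                bad_diag = np.nonzero(np.diag(Dij))[0]
                if bad_diag.size:
                    report.violations.append(
                        f"D^({i},{j}) has nonzero diagonal at drug {int(bad_diag[0])}"
                    )
                if np.any(np.triu(Dij, 1)):
                    report.violations.append(
                        f"D^({i},{j}) has entries above the diagonal; "
                        "canonical storage is strictly lower triangular"
                    )
    if model.state_labels is not None and len(model.state_labels) != n:
        report.violations.append("state_labels length does not match n")
    if model.drug_labels is not None and len(model.drug_labels) != m:
        report.violations.append("drug_labels length does not match m")
    return report


def check_state_nonnegative(x, tol: float = NEGATIVITY_TOLERANCE) -> None:
    """Diagnostic for the admissibility invariant ``x >= 0``.

    Values in ``(-tol, 0)`` are treated as integrator round-off and warn;
    anything more negative raises.  Nonnegativity is a property of admissible
    trajectories (it depends on the signs of the model's polynomial terms),
    so it is monitored rather than enforced by projection.
    """
    x = np.asarray(x, dtype=float)
    worst = float(x.min()) if x.size else 0.0
    if worst < -tol:
        raise ModelValidationError(f"state became negative: min entry {worst:.3e}")
    if worst < 0.0:
        warnings.warn(
            f"state marginally negative (min {worst:.3e}); treated as round-off",
            RuntimeWarning,
            stacklevel=2,
        )
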