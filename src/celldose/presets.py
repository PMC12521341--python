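"""Fully parameterised example systems.

Two worked systems are provided:

* **Two-population cervical cancer model** — cells split by cell-cycle phase
  into G1 (``A``) and S/G2 (``B``), treated with cisplatin (``u_c``, kills G1
  cells and blocks G1 -> S/G2 transit) and paclitaxel (``u_p``, kills S/G2
  cells and blocks division).  After rescaling time by the G1 -> S/G2 transit
  rate ``k`` the model has two dimensionless parameters, the rescaled kill
  rates ``alpha = delta_A / k`` and ``beta = delta_B / k``:

      dN_A/dtau = 2 N_B (1 - u_p) - N_A (1 - u_c) - alpha u_c N_A,
      dN_B/dtau = -N_B (1 - u_p) + N_A (1 - u_c) - beta u_p N_B.

* **Neuroblastoma model** — sympathoblast (I), adrenergic (N) and mesenchymal
  (S) sub-populations under four agents: retinoic acid (``u_RA``, drives
  I -> N differentiation), chemotherapy (``u_chemo``, kills proliferative I
  cells), a pan-trk inhibitor (``u_trk``) and NGF (``u_NGF``).  trkA + NGF
  drives I -> N differentiation, trkA without NGF drives N-cell apoptosis,
  and trkB + BDNF de-differentiates N cells into I and S; every
  ``(1 - u_trk) u_NGF``-type product expands into linear-in-u entries plus a
  genuine ``u_trk * u_NGF`` synergy.  A reduced three-parameter version
  (``lam``, ``delta``, ``delta_apop``) sets all spontaneous interconversion
  rates equal (rescaling time by them), all drug-mediated interconversion
  effects to ``delta``, and the chemotherapy kill rate to ``2 * lam``.

Population order is (I, N, S) and drug order (u_RA, u_chemo, u_trk, u_NGF)
throughout; all C/D index semantics rely on these orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ControlledODEModel, ModelValidationError
from .solver import CostSpec, OCProblem

__all__ = [
    "TwoPopulationParams",
    "NeuroblastomaFullParams",
    "NeuroblastomaReducedParams",
    "ToxicitySweepSpec",
    "build_two_population",
    "build_neuroblastoma_full",
    "reduce_neuroblastoma",
    "default_problem",
]

TWO_POP_STATES = ("N_A", "N_B")
TWO_POP_DRUGS = ("u_c", "u_p")
NB_STATES = ("n_I", "n_N", "n_S")
NB_DRUGS = ("u_RA", "u_chemo", "u_trk", "u_NGF")

#: drug indices in the neuroblastoma ordering
_RA, _CHEMO, _TRK, _NGF = 0, 1, 2, 3


@dataclass
class TwoPopulationParams:
    """Rescaled kill rates; both drawn from [0.05, 0.5] in the analyses."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ModelValidationError("alpha and beta must be positive")


def build_two_population(p: TwoPopulationParams) -> ControlledODEModel:
    """Two-population cervical-cancer model in rescaled time (B = 0, D = 0)."""
    A = np.array([[-1.0, 2.0], [1.0, -1.0]])
    C1 = np.array([[1.0 - p.alpha, 0.0], [-1.0, 0.0]])
    C2 = np.array([[0.0, -2.0], [0.0, 1.0 - p.beta]])
    return ControlledODEModel.from_terms(
        A,
        m=2,
        C=[C1, C2],
        state_labels=TWO_POP_STATES,
        drug_labels=TWO_POP_DRUGS,
    )


@dataclass
class NeuroblastomaFullParams:
    """Raw rates (per unit time) of the full three-population model."""

    lam_I: float = 0.2
    lam_N: float = 0.0
    lam_S: float = 0.0
    k_IN: float = 1.0
    k_IS: float = 1.0
    k_NI: float = 1.0
    k_SI: float = 1.0
    k_NS: float = 1.0
    k_SN: float = 1.0
    delta_RA: float = 0.1
    delta_chemo: float = 0.4
    delta_diff: float = 0.1
    delta_BDNF: float = 0.1
    delta_trk_NGF: float = 0.3

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if name.startswith("k_") and value < 0:
                raise ModelValidationError(f"interconversion rate {name} must be >= 0")
            if name.startswith("delta") and value < 0:
                raise ModelValidationError(f"drug-effect rate {name} must be >= 0")


def build_neuroblastoma_full(p: NeuroblastomaFullParams) -> ControlledODEModel:
    """Three-population neuroblastoma model with every drug pathway expanded.

    The products ``(1 - u_trk) u_NGF`` (trkA+NGF differentiation),
    ``(1 - u_trk)`` (trkB+BDNF de-differentiation, draining N with factor 2
    and feeding one unit each into I and S) and ``(1 - u_NGF)(1 - u_trk)``
    (trkA-NGF apoptosis) are expanded into drug-free entries of ``A``,
    linear-in-u entries of ``C`` and ``u_trk * u_NGF`` synergy entries of
    ``D``.
    """
    A = np.array(
        [
            [p.lam_I - (p.k_IN + p.k_IS), p.k_NI + p.delta_BDNF, p.k_SI],
            [
                p.k_IN,
                p.lam_N - (p.k_NS + p.k_NI) - p.delta_trk_NGF - 2.0 * p.delta_BDNF,
                p.k_SN,
            ],
            [p.k_IS, p.k_NS + p.delta_BDNF, p.lam_S - (p.k_SN + p.k_SI)],
        ]
    )
    C_I = np.zeros((3, 4))
    C_I[0, _RA] = -p.delta_RA
    C_I[0, _CHEMO] = -p.delta_chemo
    C_I[0, _NGF] = -p.delta_diff
    C_I[1, _RA] = p.delta_RA
    C_I[1, _NGF] = p.delta_diff
    C_N = np.zeros((3, 4))
    C_N[0, _TRK] = -p.delta_BDNF
    C_N[1, _TRK] = p.delta_trk_NGF + 2.0 * p.delta_BDNF
    C_N[1, _NGF] = p.delta_trk_NGF
    C_N[2, _TRK] = -p.delta_BDNF
    # synergies: coefficient of u_trk * u_NGF, stored at (NGF, trk) strictly lower
    D = {
        (0, 0): _pair(p.delta_diff),
        (0, 1): _pair(-p.delta_diff),
        (1, 1): _pair(-p.delta_trk_NGF),
    }
    return ControlledODEModel.from_terms(
        A,
        m=4,
        C=[C_I, C_N, np.zeros((3, 4))],
        D=D,
        state_labels=NB_STATES,
        drug_labels=NB_DRUGS,
    )


def _pair(coeff: float) -> np.ndarray:
    Dij = np.zeros((4, 4))
    Dij[_NGF, _TRK] = coeff
    return Dij


@dataclass
class NeuroblastomaReducedParams:
    """Dimensionless parameters of the reduced model (range [0.05, 0.5])."""

    lam: float = 0.2
    delta: float = 0.1
    delta_apop: float = 0.3

    def __post_init__(self):
        if min(self.lam, self.delta, self.delta_apop) <= 0:
            raise ModelValidationError(
                "lam, delta and delta_apop must all be positive"
            )


def reduce_neuroblastoma(p: NeuroblastomaReducedParams) -> ControlledODEModel:
    """Reduced neuroblastoma model in rescaled time ``tau = k t``.

    Obtained from the full model by setting every spontaneous interconversion
    rate to ``k``, every drug-mediated interconversion effect to ``delta``,
    the chemotherapy kill rate to ``2 * lam`` (full kill of the proliferative
    I compartment at maximal dose), proliferation only in I, and dividing all
    rates by ``k``.
    """
    lam, d, da = p.lam, p.delta, p.delta_apop
    A = np.array(
        [
            [lam - 2.0, 1.0 + d, 1.0],
            [1.0, -2.0 - 2.0 * d - da, 1.0],
            [1.0, 1.0 + d, -2.0],
        ]
    )
    C_I = np.array(
        [
            [-d, -2.0 * lam, 0.0, -d],
            [d, 0.0, 0.0, d],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    C_N = np.array(
        [
            [0.0, 0.0, -d, 0.0],
            [0.0, 0.0, da + 2.0 * d, da],
            [0.0, 0.0, -d, 0.0],
        ]
    )
    D = {(0, 0): _pair(d), (0, 1): _pair(-d), (1, 1): _pair(-da)}
    return ControlledODEModel.from_terms(
        A,
        m=4,
        C=[C_I, C_N, np.zeros((3, 4))],
        D=D,
        state_labels=NB_STATES,
        drug_labels=NB_DRUGS,
    )


@dataclass
class ToxicitySweepSpec:
    """Asymmetric-toxicity sweep along a path through (alpha, beta) space.

    The path ``alpha = gamma0 + gamma sin(phi)``, ``beta = gamma0 +
    gamma cos(phi)`` for ``phi in [0, 2 pi / 9]`` crosses the region where the
    cisplatin cost varies most; the total control penalty ``R0`` is split as
    ``R = diag(R_alpha, R_beta)`` with ``R_alpha + R_beta = R0``.
    """

    R0: float = 0.2
    gamma0: float = 0.05
    gamma: float = 0.4
    phi_max: float = 2.0 * np.pi / 9.0

    def path(self, phi: float) -> tuple[float, float]:
        if not 0.0 <= phi <= self.phi_max + 1e-12:
            raise ModelValidationError(f"phi must lie in [0, {self.phi_max:g}]")
        return (
            self.gamma0 + self.gamma * np.sin(phi),
            self.gamma0 + self.gamma * np.cos(phi),
        )

    def penalty(self, R_alpha: float) -> np.ndarray:
        R_beta = self.R0 - R_alpha
        if R_alpha <= 0 or R_beta <= 0:
            raise ModelValidationError("R_alpha and R_beta must be positive")
        return np.diag([R_alpha, R_beta])


#: default problem settings shared by both presets
DEFAULT_T = 7.0
DEFAULT_R_SCALE = 0.1

_PRESET_DIMS = {"two_population": 2, "neuroblastoma": 3}


def default_problem(model: ControlledODEModel, preset: str) -> OCProblem:
    """Reference problem: ``Q = I``, ``R = 0.1 I``, ``M = 0``, ``T = 7`` and an
    equal unit initial population in every compartment.

    ``T = 7`` is a standard one-week course in time rescaled by the ~24 h
    reference rate.
    """
    if preset not in _PRESET_DIMS:
        raise ModelValidationError(
            f"unknown preset {preset!r}; expected one of {sorted(_PRESET_DIMS)}"
        )
    n = _PRESET_DIMS[preset]
    if model.n != n:
        raise ModelValidationError(
            f"preset {preset!r} expects n={n}, model has n={model.n}"
        )
    cost = CostSpec(
        M=np.zeros((n, n)),
        Q=np.eye(n),
        R=DEFAULT_R_SCALE * np.eye(model.m),
        T=DEFAULT_T,
    )
    return OCProblem(model=model, cost=cost, x0=np.ones(n))
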