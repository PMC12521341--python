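"""Independent oracles used by the test suite.

Everything here is deliberately written without reusing the package's
structured-coefficient evaluation paths: scalar transcriptions of the worked
example equations, a backward-Riccati LQR solver, and finite-difference
gradients of the Hamiltonian.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def two_population_printed_rhs(alpha, beta, x, u):
    """Direct scalar transcription of the two-population rescaled ODEs."""
    NA, NB = x
    uc, up = u
    dNA = 2 * NB * (1 - up) - NA * (1 - uc) - alpha * uc * NA
    dNB = -NB * (1 - up) + NA * (1 - uc) - beta * up * NB
    return np.array([dNA, dNB])


def neuroblastoma_full_printed_rhs(p, n, u):
    """Direct scalar transcription of the full three-population model."""
    nI, nN, nS = n
    uRA, uch, utrk, uNGF = u
    dI = (
        p.lam_I * nI
        - (p.k_IN + p.k_IS) * nI
        + p.k_NI * nN
        + p.k_SI * nS
        - p.delta_RA * uRA * nI
        - p.delta_chemo * uch * nI
        - p.delta_diff * (1 - utrk) * uNGF * nI
        + p.delta_BDNF * (1 - utrk) * nN
    )
    dN = (
        p.lam_N * nN
        - (p.k_NS + p.k_NI) * nN
        + p.k_IN * nI
        + p.k_SN * nS
        + p.delta_RA * uRA * nI
        - p.delta_trk_NGF * (1 - uNGF) * (1 - utrk) * nN
        + p.delta_diff * (1 - utrk) * uNGF * nI
        - 2 * p.delta_BDNF * (1 - utrk) * nN
    )
    dS = (
        p.lam_S * nS
        - (p.k_SN + p.k_SI) * nS
        + p.k_IS * nI
        + p.k_NS * nN
        + p.delta_BDNF * (1 - utrk) * nN
    )
    return np.array([dI, dN, dS])


def neuroblastoma_reduced_printed_rhs(lam, delta, delta_apop, n, u):
    """Direct scalar transcription of the reduced three-population model."""
    nI, nN, nS = n
    uRA, uch, utrk, uNGF = u
    dI = (
        (lam - 2) * nI
        + nN
        + nS
        - (delta * uRA + 2 * lam * uch + delta * (1 - utrk) * uNGF) * nI
        + delta * (1 - utrk) * nN
    )
    dN = (
        -2 * nN
        + nI
        + nS
        + delta * (uRA + (1 - utrk) * uNGF) * nI
        - (delta_apop * (1 - uNGF) * (1 - utrk) + 2 * delta * (1 - utrk)) * nN
    )
    dS = -2 * nS + nI + nN + delta * (1 - utrk) * nN
    return np.array([dI, dN, dS])


def riccati_lqr(A, B, Q, R, M, T, x0):
    """Classical LQR via backward Riccati integration + forward closed loop.

    Returns ``(P_of_t, x_of_t)``; the optimal control is
    ``u(t) = -R^{-1} B' P(t) x(t)`` and the co-state is ``P(t) x(t)``.
    """
    n = A.shape[0]
    Rinv = np.linalg.inv(R)

    def pdot(t, p):
        P = p.reshape(n, n)
        return -(A.T @ P + P @ A - P @ B @ Rinv @ B.T @ P + Q).ravel()

    back = solve_ivp(
        lambda s, p: -pdot(T - s, p),
        (0.0, T),
        np.asarray(M, float).ravel(),
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )

    def P_of_t(t):
        return back.sol(T - t).reshape(n, n)

    fwd = solve_ivp(
        lambda t, x: (A - B @ Rinv @ B.T @ P_of_t(t)) @ x,
        (0.0, T),
        np.asarray(x0, float),
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    return P_of_t, fwd.sol


def fd_gradient(f, z, h=1e-6):
    """Central finite-difference gradient of a scalar function."""
    z = np.asarray(z, float)
    g = np.zeros(z.size)
    for i in range(z.size):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        g[i] = (f(zp) - f(zm)) / (2 * h)
    return g


def random_structured_model(rng, n_max=3, m_max=4, with_B=True):
    """A random small model with entries in [-1, 1] and canonical D storage."""
    from celldose import ControlledODEModel

    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    A = rng.uniform(-1, 1, (n, n))
    B = rng.uniform(-1, 1, (n, m)) if with_B else np.zeros((n, m))
    C = rng.uniform(-1, 1, (n, n, m))
    D = np.tril(rng.uniform(-1, 1, (n, n, m, m)), -1)
    return ControlledODEModel(A, B, C, D)
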