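"""Numba-compiled numerical kernels.

Everything here operates on a flat parameter vector (see ``PARAM_ORDER``)
so the hot loops stay free of Python objects.  The public API in
:mod:`myelopt.model`, :mod:`myelopt.simulate` and :mod:`myelopt.solver`
wraps these kernels with validation and typed containers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Index layout of the flat parameter vector.
PARAM_ORDER = (
    "beta_A",
    "rho_A",
    "mu_A",
    "mu_Au",
    "rho_P",
    "mu_P",
    "mu_Pu",
    "rho_N",
    "mu_N",
    "delta_P",
    "delta_N",
    "delta_Pu",
    "alpha",
    "gamma",
)

(
    I_BETA_A,
    I_RHO_A,
    I_MU_A,
    I_MU_AU,
    I_RHO_P,
    I_MU_P,
    I_MU_PU,
    I_RHO_N,
    I_MU_N,
    I_DELTA_P,
    I_DELTA_N,
    I_DELTA_PU,
    I_ALPHA,
    I_GAMMA,
) = range(14)


@njit(cache=True)
def rhs_arr(x, u, p):
    """Time derivative of (A, P, N) under control level ``u``."""
    A, P, N = x[0], x[1], x[2]
    space = 1.0 - A - N - P
    immune = p[I_ALPHA] / (p[I_GAMMA] + P + N)
    out = np.empty(3)
    out[0] = p[I_BETA_A] + p[I_RHO_A] * A * space - p[I_MU_A] * A - p[I_MU_AU] * u * A
    out[1] = (
        p[I_RHO_P] * P * space
        - p[I_DELTA_P] * P
        + p[I_DELTA_N] * N
        - p[I_DELTA_PU] * u * P
        - p[I_MU_P] * P
        - p[I_MU_PU] * u * P
        - immune * P
    )
    out[2] = (
        p[I_RHO_N] * N * space
        + p[I_DELTA_P] * P
        - p[I_DELTA_N] * N
        + p[I_DELTA_PU] * u * P
        - p[I_MU_N] * N
        - immune * N
    )
    return out


@njit(cache=True)
def jacobian_arr(x, u, p):
    """Jacobian d(rhs)/d(A, P, N), 3x3."""
    A, P, N = x[0], x[1], x[2]
    space = 1.0 - A - N - P
    denom = p[I_GAMMA] + P + N
    alpha = p[I_ALPHA]
    J = np.empty((3, 3))
    # dA'/d*
    J[0, 0] = p[I_RHO_A] * (space - A) - p[I_MU_A] - p[I_MU_AU] * u
    J[0, 1] = -p[I_RHO_A] * A
    J[0, 2] = -p[I_RHO_A] * A
    # dP'/d*
    J[1, 0] = -p[I_RHO_P] * P
    J[1, 1] = (
        p[I_RHO_P] * (space - P)
        - p[I_DELTA_P]
        - p[I_DELTA_PU] * u
        - p[I_MU_P]
        - p[I_MU_PU] * u
        - alpha * (p[I_GAMMA] + N) / (denom * denom)
    )
    J[1, 2] = -p[I_RHO_P] * P + p[I_DELTA_N] + alpha * P / (denom * denom)
    # dN'/d*
    J[2, 0] = -p[I_RHO_N] * N
    J[2, 1] = -p[I_RHO_N] * N + p[I_DELTA_P] + p[I_DELTA_PU] * u + alpha * N / (denom * denom)
    J[2, 2] = (
        p[I_RHO_N] * (space - N)
        - p[I_DELTA_N]
        - p[I_MU_N]
        - alpha * (p[I_GAMMA] + P) / (denom * denom)
    )
    return J


@njit(cache=True)
def integrate_rk4(p, x0, u, dt):
    """Classical fixed-step RK4 over the node grid carrying ``u``.

    The control is interpolated linearly, so the half-step value for step
    ``i`` is ``(u[i] + u[i+1]) / 2``.  Returns the (n, 3) state array and
    the index of the first non-finite step (-1 when the run is clean).
    """
    n = u.shape[0]
    X = np.empty((n, 3))
    X[0] = x0
    x = x0.copy()
    for i in range(n - 1):
        um = 0.5 * (u[i] + u[i + 1])
        k1 = rhs_arr(x, u[i], p)
        k2 = rhs_arr(x + 0.5 * dt * k1, um, p)
        k3 = rhs_arr(x + 0.5 * dt * k2, um, p)
        k4 = rhs_arr(x + dt * k3, u[i + 1], p)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not (np.isfinite(x[0]) and np.isfinite(x[1]) and np.isfinite(x[2])):
            X[i + 1] = x
            return X, i + 1
        X[i + 1] = x
    return X, -1


@njit(cache=True)
def adjoint_rhs_arr(x, lam, u, p, w_c_lin, w_c_quad):
    """Costate derivative lambda' = -dH/dx for running cost with cancer
    weights ``w_c_lin * (P+N) + w_c_quad * (P+N)^2``."""
    P, N = x[1], x[2]
    dLdPN = w_c_lin + 2.0 * w_c_quad * (P + N)
    J = jacobian_arr(x, u, p)
    out = np.empty(3)
    # dH/dA = dL/dA + lam . df/dA  (dL/dA = 0)
    out[0] = -(lam[0] * J[0, 0] + lam[1] * J[1, 0] + lam[2] * J[2, 0])
    out[1] = -(dLdPN + lam[0] * J[0, 1] + lam[1] * J[1, 1] + lam[2] * J[2, 1])
    out[2] = -(dLdPN + lam[0] * J[0, 2] + lam[1] * J[1, 2] + lam[2] * J[2, 2])
    return out


@njit(cache=True)
def adjoint_backward_rk4(p, X, u, dt, w_c_lin, w_c_quad):
    """Integrate the costate backwards from lambda(tf) = 0 with RK4.

    The stored forward state is interpolated linearly for half-steps.
    Returns the (n, 3) costate array aligned with the forward grid.
    """
    n = u.shape[0]
    L = np.empty((n, 3))
    lam = np.zeros(3)
    L[n - 1] = lam
    for i in range(n - 1, 0, -1):
        xm = 0.5 * (X[i] + X[i - 1])
        um = 0.5 * (u[i] + u[i - 1])
        k1 = adjoint_rhs_arr(X[i], lam, u[i], p, w_c_lin, w_c_quad)
        k2 = adjoint_rhs_arr(xm, lam - 0.5 * dt * k1, um, p, w_c_lin, w_c_quad)
        k3 = adjoint_rhs_arr(xm, lam - 0.5 * dt * k2, um, p, w_c_lin, w_c_quad)
        k4 = adjoint_rhs_arr(X[i - 1], lam - dt * k3, u[i - 1], p, w_c_lin, w_c_quad)
        lam = lam - (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        L[i - 1] = lam
    return L


@njit(cache=True)
def adjoint_forward_rk4(p, X, u, dt, w_c_lin, w_c_quad, lam0):
    """Integrate the costate forwards from ``lam0`` (round-trip check)."""
    n = u.shape[0]
    L = np.empty((n, 3))
    lam = lam0.copy()
    L[0] = lam
    for i in range(n - 1):
        xm = 0.5 * (X[i] + X[i + 1])
        um = 0.5 * (u[i] + u[i + 1])
        k1 = adjoint_rhs_arr(X[i], lam, u[i], p, w_c_lin, w_c_quad)
        k2 = adjoint_rhs_arr(xm, lam + 0.5 * dt * k1, um, p, w_c_lin, w_c_quad)
        k3 = adjoint_rhs_arr(xm, lam + 0.5 * dt * k2, um, p, w_c_lin, w_c_quad)
        k4 = adjoint_rhs_arr(X[i + 1], lam + dt * k3, u[i + 1], p, w_c_lin, w_c_quad)
        lam = lam + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        L[i + 1] = lam
    return L
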