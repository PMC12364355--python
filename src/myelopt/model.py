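"""Three-compartment bone-marrow model: healthy cells (A), CD38+ myeloma (P)
and CD38- myeloma (N), all measured as fractions of the marrow carrying
capacity.

The dynamics couple logistic space competition shared by all three
populations, reversible CD38 expression switching between P and N, three
drug actions (mortality of P, drug-induced P->N switching, off-target
mortality of A) and a saturating Michaelis-Menten immune removal of the
cancer compartments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from ._kernels import PARAM_ORDER, integrate_rk4, jacobian_arr, rhs_arr

__all__ = [
    "ModelParameters",
    "SystemState",
    "default_parameters",
    "null_n_parameters",
    "rhs",
    "jacobian",
    "healthy_equilibrium",
    "cancerous_equilibrium",
    "EquilibriumError",
]


class EquilibriumError(RuntimeError):
    """Raised when a requested fixed point does not exist or is not reached."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the controlled system.

    All rates are non-negative and carry abstract time units; ``gamma`` is
    a population fraction and must be positive so the immune term stays
    finite at zero cancer load.
    """

    beta_A: float    # influx of healthy cells
    rho_A: float     # proliferation rate of A
    mu_A: float      # death/exit rate of A
    mu_Au: float     # off-target mortality of A per unit control
    rho_P: float     # proliferation rate of P
    mu_P: float      # death/exit rate of P
    mu_Pu: float     # drug mortality of P per unit control (sets control scale)
    rho_N: float     # proliferation rate of N
    mu_N: float      # death/exit rate of N
    delta_P: float   # P -> N expression-loss rate
    delta_N: float   # N -> P expression-gain rate
    delta_Pu: float  # drug-induced P -> N rate per unit control
    alpha: float     # immune control rate
    gamma: float     # immune half-saturation (fraction of capacity)

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")

    def to_array(self) -> np.ndarray:
        """Flat float vector in kernel order (see ``_kernels.PARAM_ORDER``)."""
        return np.array([float(getattr(self, name)) for name in PARAM_ORDER])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelParameters":
        return cls(**{name: float(v) for name, v in zip(PARAM_ORDER, values, strict=True)})

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_ORDER}

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        unknown = set(mapping) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAM_ORDER) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **overrides: float) -> "ModelParameters":
        """New parameter set with the given fields overridden."""
        unknown = set(overrides) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class SystemState:
    """Population triple (A, P, N), each a fraction of carrying capacity."""

    A: float
    P: float
    N: float

    def __post_init__(self) -> None:
        for name in ("A", "P", "N"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"state component {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"state component {name} must be >= 0, got {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.A, self.P, self.N], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, clip_tol: float = 1e-9) -> "SystemState":
        """Build from a length-3 vector, forgiving round-off negatives up to
        ``clip_tol``."""
        vals = np.asarray(values, dtype=float)
        if vals.shape != (3,):
            raise ValueError(f"expected a length-3 vector, got shape {vals.shape}")
        if np.any(vals < -clip_tol):
            raise ValueError(f"state components below -{clip_tol:g}: {vals!r}")
        vals = np.clip(vals, 0.0, None)
        return cls(A=float(vals[0]), P=float(vals[1]), N=float(vals[2]))

    @property
    def cancer(self) -> float:
        return self.P + self.N


def default_parameters() -> ModelParameters:
    """Full-model default parameter set."""
    return ModelParameters(
        beta_A=0.1008,
        rho_A=0.43,
        mu_A=0.44,
        mu_Au=0.1,
        rho_P=0.28,
        mu_P=0.048,
        mu_Pu=1.0,
        rho_N=0.15,
        mu_N=0.06,
        delta_P=0.003,
        delta_N=0.03,
        delta_Pu=0.2,
        alpha=0.015,
        gamma=0.1,
    )


def null_n_parameters() -> ModelParameters:
    """Reduced negative-control parameter set with the N compartment and
    off-target effect switched off (paired with the initial condition
    N(0) = 0, under which dN/dt vanishes identically)."""
    return ModelParameters(
        beta_A=0.1008,
        rho_A=0.43,
        mu_A=0.44,
        mu_Au=0.0,
        rho_P=0.27,
        mu_P=0.05,
        mu_Pu=1.0,
        rho_N=0.0,
        mu_N=0.0,
        delta_P=0.0,
        delta_N=0.0,
        delta_Pu=0.0,
        alpha=0.015,
        gamma=0.1,
    )


def _check_rhs_inputs(state: SystemState, u: float) -> None:
    if not math.isfinite(u):
        raise ValueError(f"control level must be finite, got {u!r}")
    if u < 0:
        raise ValueError(f"control level must be >= 0, got {u!r}")
    for name in ("A", "P", "N"):
        if not math.isfinite(getattr(state, name)):
            raise ValueError(f"state component {name} is not finite")


def rhs(state: SystemState, u: float, params: ModelParameters) -> tuple[float, float, float]:
    """Right-hand side (dA/dt, dP/dt, dN/dt) at ``state`` under control ``u``.

    The three equations share the space-competition factor
    ``1 - A - N - P`` and the immune denominator ``gamma + P + N``.
    """
    _check_rhs_inputs(state, u)
    out = rhs_arr(state.to_array(), float(u), params.to_array())
    return float(out[0]), float(out[1]), float(out[2])


def jacobian(state: SystemState, u: float, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to (A, P, N)."""
    _check_rhs_inputs(state, u)
    return np.asarray(jacobian_arr(state.to_array(), float(u), params.to_array()))


def healthy_equilibrium(params: ModelParameters) -> SystemState:
    """Cancer-free fixed point (A*, 0, 0).

    A* is the positive root of ``beta_A + rho_A*A*(1-A) - mu_A*A = 0``.
    """
    if params.rho_A <= 0:
        raise EquilibriumError("healthy equilibrium requires rho_A > 0")
    # rho_A*A^2 + (mu_A - rho_A)*A - beta_A = 0
    a = params.rho_A
    b = params.mu_A - params.rho_A
    c = -params.beta_A
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise EquilibriumError("no real root for the healthy equilibrium")
    root = (-b + math.sqrt(disc)) / (2.0 * a)
    if root < 0:
        raise EquilibriumError("no non-negative root for the healthy equilibrium")
    state = SystemState(A=root, P=0.0, N=0.0)
    residual = max(abs(v) for v in rhs(state, 0.0, params))
    if residual > 1e-12:
        raise EquilibriumError(f"healthy equilibrium residual {residual:g} exceeds 1e-12")
    return state


def _newton_polish(
    p: np.ndarray,
    x: np.ndarray,
    u: float,
    tol: float = 1e-13,
    max_steps: int = 50,
) -> np.ndarray:
    """Damped Newton iteration on the rhs using the analytic Jacobian."""
    for _ in range(max_steps):
        f = rhs_arr(x, u, p)
        if float(np.max(np.abs(f))) < tol:
            return x
        J = jacobian_arr(x, u, p)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        base = float(np.max(np.abs(f)))
        for _damp in range(30):
            cand = x + scale * step
            if np.all(cand > -1e-12):
                fc = rhs_arr(np.clip(cand, 0.0, None), u, p)
                if float(np.max(np.abs(fc))) < base:
                    x = np.clip(cand, 0.0, None)
                    break
            scale *= 0.5
        else:
            break
    return x


def cancerous_equilibrium(
    params: ModelParameters,
    t_max: float = 5000.0,
    dt: float = 0.01,
    tol: float = 1e-12,
) -> SystemState:
    """Persistent-cancer steady state reached from (A, P, N) = (0, 0.1, 0)
    with no control; used as the default initial state for the control
    problems.

    Found by long simulation followed by a damped Newton polish of the rhs
    (target residual 1e-12, required < 1e-10).
    """
    p = params.to_array()
    x = np.array([0.0, 0.1, 0.0])
    chunk = 100.0
    n_chunk = int(round(chunk / dt)) + 1
    u = np.zeros(n_chunk)
    t = 0.0
    while t < t_max:
        X, bad = integrate_rk4(p, x, u, dt)
        if bad >= 0:
            raise EquilibriumError(f"non-finite state at t={t + bad * dt:g}")
        x = np.clip(X[-1], 0.0, None)
        t += chunk
        if float(np.max(np.abs(rhs_arr(x, 0.0, p)))) < 1e-9:
            break
    x = _newton_polish(p, x, 0.0, tol=tol)
    residual = float(np.max(np.abs(rhs_arr(x, 0.0, p))))
    if residual > 1e-10:
        raise EquilibriumError(
            f"cancerous equilibrium not converged: residual {residual:g} after t={t:g}"
        )
    state = SystemState.from_array(x)
    if state.P <= 0:
        raise EquilibriumError("no persistent-cancer state found (P = 0 at convergence)")
    return state
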