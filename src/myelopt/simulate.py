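"""Fixed-step RK4 integration of the controlled system and the trajectory /
control containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import integrate_rk4, rhs_arr
from .model import ModelParameters, SystemState

__all__ = [
    "TimeGrid",
    "Trajectory",
    "ControlSignal",
    "SteadyStateResult",
    "IntegrationError",
    "integrate",
    "find_steady_state",
]

#: default step for forward simulations
DEFAULT_DT = 0.001
#: default step for optimal-control solves
SOLVER_DT = 0.005


class IntegrationError(RuntimeError):
    """Raised when the integrator meets a non-finite state."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


@dataclass(frozen=True)
class TimeGrid:
    """Uniform node grid on [t0, tf] with step dt."""

    t0: float
    tf: float
    dt: float

    def __post_init__(self) -> None:
        if not (self.tf > self.t0):
            raise ValueError(f"need tf > t0, got t0={self.t0!r}, tf={self.tf!r}")
        if not (self.dt > 0):
            raise ValueError(f"need dt > 0, got {self.dt!r}")
        span = self.tf - self.t0
        steps = span / self.dt
        if abs(steps - round(steps)) > 1e-6 * max(1.0, steps):
            raise ValueError(
                f"(tf - t0)/dt = {steps!r} is not an integer; choose a commensurate dt"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.tf - self.t0) / self.dt))

    @property
    def n_nodes(self) -> int:
        return self.n_steps + 1

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_nodes)

    def refined(self, factor: int = 2) -> "TimeGrid":
        return TimeGrid(self.t0, self.tf, self.dt / factor)

    def index_of(self, t: float) -> int:
        """Nearest node index for time ``t`` (must lie on the grid span)."""
        if t < self.t0 - 1e-9 or t > self.tf + 1e-9:
            raise ValueError(f"time {t!r} outside grid [{self.t0}, {self.tf}]")
        return int(round((t - self.t0) / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """States on a time grid, one row per node, columns (A, P, N)."""

    grid: TimeGrid
    states: np.ndarray
    #: slack allowed below zero before a trajectory is rejected
    NEG_TOL = 1e-9

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "states", states)
        if states.shape != (self.grid.n_nodes, 3):
            raise ValueError(
                f"states shape {states.shape} does not match grid with "
                f"{self.grid.n_nodes} nodes"
            )
        if not np.all(np.isfinite(states)):
            raise ValueError("trajectory contains non-finite values")
        low = float(states.min())
        if low < -self.NEG_TOL:
            raise ValueError(f"trajectory dips below -{self.NEG_TOL:g} (min {low:g})")

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def clipped(self) -> np.ndarray:
        """States with numerical negatives snapped to zero."""
        return np.clip(self.states, 0.0, None)

    def to_frame(self, control: "ControlSignal | None" = None) -> pd.DataFrame:
        data = {
            "time": self.grid.times(),
            "A": self.A,
            "P": self.P,
            "N": self.N,
        }
        if control is not None:
            if control.grid != self.grid:
                raise ValueError("control grid does not match trajectory grid")
            data["u"] = control.values
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ControlSignal:
    """Control levels on a time grid with box bounds [lower, upper]."""

    grid: TimeGrid
    values: np.ndarray
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"control shape {values.shape} does not match grid with "
                f"{self.grid.n_nodes} nodes"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("control contains non-finite values")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        tol = 1e-12
        if float(values.min()) < self.lower - tol or float(values.max()) > self.upper + tol:
            raise ValueError(
                f"control values outside bounds [{self.lower}, {self.upper}]"
            )

    @classmethod
    def constant(
        cls, grid: TimeGrid, level: float, lower: float = 0.0, upper: float | None = None
    ) -> "ControlSignal":
        if upper is None:
            upper = max(1.0, level)
        return cls(grid, np.full(grid.n_nodes, float(level)), lower=lower, upper=upper)

    def with_values(self, values: np.ndarray) -> "ControlSignal":
        return ControlSignal(self.grid, values, lower=self.lower, upper=self.upper)


def integrate(
    params: ModelParameters,
    x0: SystemState,
    control: ControlSignal,
    grid: TimeGrid | None = None,
) -> Trajectory:
    """Integrate the model with classical RK4 on the control's grid.

    The control is piecewise-linear between nodes; half-step evaluations
    use the midpoint of adjacent node values.
    """
    if grid is not None and grid != control.grid:
        raise ValueError("explicit grid does not match the control's grid")
    grid = control.grid
    X, bad = integrate_rk4(
        params.to_array(), x0.to_array(), np.asarray(control.values, dtype=float), grid.dt
    )
    if bad >= 0:
        raise IntegrationError(
            f"non-finite state at step {bad} (t = {grid.t0 + bad * grid.dt:g})", bad
        )
    return Trajectory(grid, X)


@dataclass(frozen=True)
class SteadyStateResult:
    state: SystemState
    converged: bool
    residual: float
    elapsed: float


def find_steady_state(
    params: ModelParameters,
    x0: SystemState,
    u_const: float = 0.0,
    tol: float = 1e-10,
    t_max: float = 5000.0,
    dt: float = 0.01,
    chunk: float = 50.0,
) -> SteadyStateResult:
    """Simulate under constant control until ``||rhs||_inf < tol`` or
    ``t_max`` is reached; non-convergence is reported via the flag."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    p = params.to_array()
    x = x0.to_array()
    residual = float(np.max(np.abs(rhs_arr(x, u_const, p))))
    t = 0.0
    n_chunk = int(round(chunk / dt)) + 1
    u = np.full(n_chunk, float(u_const))
    while residual >= tol and t < t_max:
        X, bad = integrate_rk4(p, x, u, dt)
        if bad >= 0:
            raise IntegrationError(f"non-finite state near t={t + bad * dt:g}", bad)
        x = np.clip(X[-1], 0.0, None)
        t += chunk
        residual = float(np.max(np.abs(rhs_arr(x, u_const, p))))
    return SteadyStateResult(
        state=SystemState.from_array(x),
        converged=residual < tol,
        residual=residual,
        elapsed=t,
    )
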