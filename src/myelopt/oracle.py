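"""Independent brute-force validation of the sweep solver on small
instances: direct transcription over piecewise-constant controls, and
finite-difference objective gradients."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._kernels import integrate_rk4
from .cost import CostSpec
from .model import ModelParameters, SystemState
from .simulate import ControlSignal

__all__ = [
    "TranscriptionSpec",
    "OracleError",
    "direct_transcription_optimum",
    "finite_difference_gradient",
]


class OracleError(RuntimeError):
    def __init__(self, message: str, restart_log: list):
        super().__init__(message)
        self.restart_log = restart_log


@dataclass(frozen=True)
class TranscriptionSpec:
    """Piecewise-constant transcription of a small control problem."""

    n_segments: int
    horizon: float
    dt: float = 0.005
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.n_segments > 40:
            raise ValueError("transcription capped at 40 segments (desk-scale guard)")
        if not (0 < self.horizon <= 50):
            raise ValueError("transcription horizon capped at 50 (desk-scale guard)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def _expand_segments(seg_values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Node control vector for piecewise-constant segments tiling the grid."""
    m = seg_values.shape[0]
    # node i at time i*dt belongs to segment floor(i * m / (n-1)), last node in last segment
    idx = np.minimum((np.arange(n_nodes) * m) // (n_nodes - 1), m - 1)
    return seg_values[idx]


def _objective(
    p: np.ndarray, x0: np.ndarray, spec: CostSpec, dt: float, n_nodes: int
) -> "callable":
    def J(seg_values: np.ndarray) -> float:
        u = _expand_segments(np.asarray(seg_values, dtype=float), n_nodes)
        X, bad = integrate_rk4(p, x0, u, dt)
        if bad >= 0:
            return 1e9
        c = X[:, 1] + X[:, 2]
        L = (
            spec.w_u_lin * u
            + spec.w_u_quad * u * u
            + spec.w_c_lin * c
            + spec.w_c_quad * c * c
        )
        return float(np.trapezoid(L, dx=dt))

    return J


def direct_transcription_optimum(
    params: ModelParameters,
    x0: SystemState,
    spec: CostSpec,
    tspec: TranscriptionSpec,
) -> tuple[np.ndarray, float]:
    """Minimise J over piecewise-constant controls with a general bounded
    optimiser (L-BFGS-B) from multiple restarts; returns the best
    (segment values, J) found."""
    n_nodes = int(round(tspec.horizon / tspec.dt)) + 1
    J = _objective(params.to_array(), x0.to_array(), spec, tspec.dt, n_nodes)
    m = tspec.n_segments
    bounds = [(spec.u_min, spec.u_max)] * m

    rng = np.random.default_rng(tspec.seed)
    starts = [np.zeros(m), np.full(m, 0.5 * min(1.0, spec.u_max))]
    while len(starts) < tspec.restarts:
        starts.append(rng.uniform(spec.u_min, min(1.0, spec.u_max), size=m))
    starts = starts[: max(tspec.restarts, 1)]

    best = None
    log = []
    for k, s0 in enumerate(starts):
        res = minimize(J, s0, method="L-BFGS-B", bounds=bounds)
        log.append(
            {"restart": k, "success": bool(res.success), "fun": float(res.fun),
             "message": str(res.message)}
        )
        if best is None or res.fun < best[1]:
            best = (np.asarray(res.x, dtype=float), float(res.fun))
    if best is None or not any(entry["success"] for entry in log):
        raise OracleError("all transcription restarts failed", log)
    return best


def finite_difference_gradient(
    params: ModelParameters,
    x0: SystemState,
    control: ControlSignal,
    spec: CostSpec,
    node: int,
    eps: float = 1e-4,
) -> float:
    """Central difference of the simulated total cost with respect to a
    single control node."""
    if not (1e-6 <= eps <= 1e-2):
        raise ValueError("eps must lie in [1e-6, 1e-2]")
    p = params.to_array()
    x0_arr = x0.to_array()
    dt = control.grid.dt
    n = control.grid.n_nodes
    if not (0 <= node < n):
        raise ValueError(f"node {node} outside grid with {n} nodes")

    def total(u: np.ndarray) -> float:
        X, bad = integrate_rk4(p, x0_arr, u, dt)
        if bad >= 0:
            raise RuntimeError("integration failed during finite differencing")
        c = X[:, 1] + X[:, 2]
        L = (
            spec.w_u_lin * u
            + spec.w_u_quad * u * u
            + spec.w_c_lin * c
            + spec.w_c_quad * c * c
        )
        return float(np.trapezoid(L, dx=dt))

    up = np.asarray(control.values, dtype=float).copy()
    um = up.copy()
    up[node] += eps
    um[node] -= eps
    return (total(up) - total(um)) / (2.0 * eps)
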