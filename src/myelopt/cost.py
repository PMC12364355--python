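"""Running-cost functionals, trapezoidal cost evaluation and the reporting
decomposition (control cost vs cancer burden, with the burden allocated
between the CD38+ and CD38- compartments)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ControlSignal, Trajectory

__all__ = [
    "CostSpec",
    "CostBreakdown",
    "running_cost",
    "evaluate_cost",
    "initial_max_duration",
    "DEFAULT_REPORT_WINDOWS",
    "TOL_BANG",
]

#: reporting windows (upper endpoints, from t0) used in summary tables
DEFAULT_REPORT_WINDOWS = (5.0, 20.0, 50.0, 100.0)

#: tolerance below the upper bound for "control at maximum" detection
TOL_BANG = 1e-3

#: cap on the control for forms without an intrinsic upper bound
QUADRATIC_U_CAP = 10.0


@dataclass(frozen=True)
class CostSpec:
    """Specification of the running cost

    ``L = w_u_lin*u + w_u_quad*u^2 + w_c_lin*(P+N) + w_c_quad*(P+N)^2``

    with zero terminal cost. The linear form bounds the control to
    [0, 1]; other forms use a configurable cap.
    """

    form: str
    w_u_lin: float = 0.0
    w_u_quad: float = 0.0
    w_c_lin: float = 0.0
    w_c_quad: float = 0.0
    u_min: float = 0.0
    u_max: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "quadratic", "mixed"):
            raise ValueError(f"unknown cost form {self.form!r}")
        for name in ("w_u_lin", "w_u_quad", "w_c_lin", "w_c_quad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.form == "linear":
            if (self.w_u_lin, self.w_c_lin) != (1.0, 1.0) or (
                self.w_u_quad,
                self.w_c_quad,
            ) != (0.0, 0.0):
                raise ValueError("linear form fixes weights (1,0,1,0)")
            if (self.u_min, self.u_max) != (0.0, 1.0):
                raise ValueError("linear form fixes control bounds [0, 1]")
        if self.form == "quadratic":
            if (self.w_u_quad, self.w_c_quad) != (1.0, 1.0) or (
                self.w_u_lin,
                self.w_c_lin,
            ) != (0.0, 0.0):
                raise ValueError("quadratic form fixes weights (0,1,0,1)")
        if not (self.u_max > self.u_min >= 0.0):
            raise ValueError("need u_max > u_min >= 0")

    @classmethod
    def linear(cls) -> "CostSpec":
        return cls(form="linear", w_u_lin=1.0, w_c_lin=1.0, u_max=1.0)

    @classmethod
    def quadratic(cls, u_max: float = QUADRATIC_U_CAP) -> "CostSpec":
        return cls(form="quadratic", w_u_quad=1.0, w_c_quad=1.0, u_max=u_max)

    @classmethod
    def mixed(
        cls,
        w_u_lin: float,
        w_u_quad: float,
        w_c_lin: float,
        w_c_quad: float,
        u_max: float = QUADRATIC_U_CAP,
    ) -> "CostSpec":
        return cls(
            form="mixed",
            w_u_lin=w_u_lin,
            w_u_quad=w_u_quad,
            w_c_lin=w_c_lin,
            w_c_quad=w_c_quad,
            u_max=u_max,
        )

    @classmethod
    def from_name(cls, name: str, u_max: float | None = None) -> "CostSpec":
        if name == "linear":
            return cls.linear()
        if name == "quadratic":
            return cls.quadratic() if u_max is None else cls.quadratic(u_max)
        raise ValueError(f"unknown cost form name {name!r}")

    def control_integrand(self, u: np.ndarray) -> np.ndarray:
        return self.w_u_lin * u + self.w_u_quad * u * u

    def cancer_integrand(self, c: np.ndarray) -> np.ndarray:
        return self.w_c_lin * c + self.w_c_quad * c * c


@dataclass(frozen=True)
class CostBreakdown:
    """Decomposition of the total cost J for reporting."""

    total: float
    control_cost: float
    cancer_burden: float
    cancer_burden_P: float
    cancer_burden_N: float
    #: control-cost integrals over [t0, t0+w] keyed by window length
    control_windows: dict = field(default_factory=dict)
    #: length of the initial run at maximum control
    initial_u_duration: float = 0.0

    def to_record(self, prefix: str = "") -> dict:
        rec = {
            f"{prefix}total": self.total,
            f"{prefix}control_cost": self.control_cost,
            f"{prefix}cancer_burden": self.cancer_burden,
            f"{prefix}cancer_burden_P": self.cancer_burden_P,
            f"{prefix}cancer_burden_N": self.cancer_burden_N,
            f"{prefix}initial_u_duration": self.initial_u_duration,
        }
        for w, v in sorted(self.control_windows.items()):
            rec[f"{prefix}control_cost_0_{w:g}"] = v
        return rec


def running_cost(state, u: float, spec: CostSpec) -> float:
    """Instantaneous running cost L(state, u)."""
    c = float(state.P + state.N) if hasattr(state, "P") else float(state[1] + state[2])
    return float(
        spec.w_u_lin * u + spec.w_u_quad * u * u + spec.w_c_lin * c + spec.w_c_quad * c * c
    )


def _trapz(y: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(y, dx=dt))


def evaluate_cost(
    trajectory: Trajectory,
    control: ControlSignal,
    spec: CostSpec,
    report_windows: tuple[float, ...] | None = None,
) -> CostBreakdown:
    """Trapezoidal quadrature of the running cost and its components.

    The cancer burden is split between P and N in proportion to their
    instantaneous contribution: at each node the integrand
    ``w_c_lin*(P+N) + w_c_quad*(P+N)^2`` is allocated by the ratio P : N.
    """
    if trajectory.grid != control.grid:
        raise ValueError("trajectory and control must share a grid")
    grid = trajectory.grid
    span = grid.tf - grid.t0
    if report_windows is None:
        windows = tuple(w for w in DEFAULT_REPORT_WINDOWS if w <= span + 1e-9)
    else:
        windows = tuple(float(w) for w in report_windows)
        for w in windows:
            if w > span + 1e-9:
                raise ValueError(f"report window {w:g} exceeds the grid span {span:g}")

    u = control.values
    P = trajectory.P
    N = trajectory.N
    c = P + N
    u_int = spec.control_integrand(u)
    c_int = spec.cancer_integrand(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_frac = np.where(c > 0, P / np.where(c > 0, c, 1.0), 0.0)
    p_share = c_int * p_frac
    n_share = c_int - p_share

    dt = grid.dt
    control_cost = _trapz(u_int, dt)
    cancer_burden = _trapz(c_int, dt)
    burden_p = _trapz(p_share, dt)
    burden_n = cancer_burden - burden_p
    window_costs = {}
    for w in windows:
        k = grid.index_of(grid.t0 + w)
        window_costs[w] = _trapz(u_int[: k + 1], dt)

    return CostBreakdown(
        total=control_cost + cancer_burden,
        control_cost=control_cost,
        cancer_burden=cancer_burden,
        cancer_burden_P=burden_p,
        cancer_burden_N=burden_n,
        control_windows=window_costs,
        initial_u_duration=initial_max_duration(control),
    )


def initial_max_duration(control: ControlSignal, tol_bang: float = TOL_BANG) -> float:
    """Length of the initial run on which the control sits at its upper
    bound: the largest T such that every node in [t0, t0+T] exceeds
    ``upper - tol_bang``.  Returns 0 when the first node is already below
    the threshold."""
    at_max = control.values > control.upper - tol_bang
    if not at_max[0]:
        return 0.0
    below = np.flatnonzero(~at_max)
    if below.size == 0:
        return control.grid.tf - control.grid.t0
    return float((below[0] - 1) * control.grid.dt)
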