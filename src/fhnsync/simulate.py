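"""Time integration of the coupled-neuron system and trajectory handling.

The implicit derivative coupling is resolved algebraically in the model
layer, so the system is integrated with an ordinary adaptive Runge-Kutta
solver (:func:`scipy.integrate.solve_ivp`).  Derived signals (the
synchronization error, its resolved rate, and the natural and supervisory
control currents) are recomputed from the exact right-hand side at every
output sample — never by finite-differencing the stored states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    ModelConfig,
    SystemState,
    fhn_cubic,
    mass_determinant,
    stimulus_current,
)

__all__ = [
    "SolverOptions",
    "Trajectory",
    "IntegrationFailureError",
    "DEFAULT_INITIAL_STATE",
    "simulate",
    "error_signal",
]

#: Default initial condition: the neurons start in distinct states so that
#: synchronization is a nontrivial event, z starts at 0 by construction.
DEFAULT_INITIAL_STATE = SystemState(x1=0.1, y1=0.1, x2=0.0, y2=0.0, z=0.0)

TRAJECTORY_COLUMNS = ["t", "x1", "y1", "x2", "y2", "z", "e", "edot", "u_pid", "u_s"]


class IntegrationFailureError(RuntimeError):
    """The ODE solver failed (step-size underflow or non-finite state)."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive integrator settings and output grid.

    method   any solve_ivp method label (default RK45)
    rtol / atol  solver tolerances
    dt_out   spacing of the output sample grid (time units)
    horizon  final time of the integration window [0, horizon]
    """

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.05
    horizon: float = 200.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.dt_out <= 0:
            raise ValueError(f"dt_out must be > 0, got {self.dt_out}")

    def grid(self) -> np.ndarray:
        t = np.arange(0.0, self.horizon + 0.5 * self.dt_out, self.dt_out)
        if t[-1] > self.horizon:
            t[-1] = self.horizon
        elif t[-1] < self.horizon:
            t = np.append(t, self.horizon)
        return t


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution with derived synchronization and control signals."""

    t: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x2: np.ndarray
    y2: np.ndarray
    z: np.ndarray
    e: np.ndarray
    edot: np.ndarray
    u_pid: np.ndarray
    u_s: np.ndarray
    config: ModelConfig = field(repr=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.t)

    def state_at(self, k: int) -> SystemState:
        return SystemState(
            x1=float(self.x1[k]), y1=float(self.y1[k]),
            x2=float(self.x2[k]), y2=float(self.y2[k]), z=float(self.z[k]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRAJECTORY_COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs_factory(cfg: ModelConfig):
    """Closure over plain floats for a fast scalar right-hand side."""
    r1, b1, v1 = cfg.neuron1.r, cfg.neuron1.b, cfg.neuron1.v
    r2, b2, v2 = cfg.neuron2.r, cfg.neuron2.b, cfg.neuron2.v
    a_over_w, w = cfg.stimulus.a / cfg.stimulus.omega, cfg.stimulus.omega
    kp, ki, kd = cfg.coupling.kp, cfg.coupling.ki, cfg.coupling.kd
    kps, kis, kds = cfg.supervisory.kp_s, cfg.supervisory.ki_s, cfg.supervisory.kd_s
    det = mass_determinant(kd, kds)
    cos = math.cos

    def rhs(t, y):
        x1, y1, x2, y2, z = y
        e = x1 - x2
        s = a_over_w * cos(w * t)
        F1 = x1 * (x1 - 1.0) * (1.0 - r1 * x1) - y1 + s - kp * e - ki * z
        F2 = x2 * (x2 - 1.0) * (1.0 - r2 * x2) - y2 + s + (kp + kps) * e + (ki + kis) * z
        edot = (F1 - F2) / det
        dx1 = F1 - kd * edot
        return (dx1, b1 * x1 + v1 * y1, dx1 - edot, b2 * x2 + v2 * y2, e)

    return rhs


def _derived_signals(t: np.ndarray, Y: np.ndarray, cfg: ModelConfig):
    """Vectorized re-evaluation of e, edot, u_pid, u_s on the sample grid."""
    x1, y1, x2, y2, z = Y
    e = x1 - x2
    s = stimulus_current(t, cfg.stimulus)
    kp, ki, kd = cfg.coupling.kp, cfg.coupling.ki, cfg.coupling.kd
    kps, kis, kds = cfg.supervisory.kp_s, cfg.supervisory.ki_s, cfg.supervisory.kd_s
    F1 = fhn_cubic(x1, cfg.neuron1.r) - y1 + s - kp * e - ki * z
    F2 = fhn_cubic(x2, cfg.neuron2.r) - y2 + s + (kp + kps) * e + (ki + kis) * z
    edot = (F1 - F2) / mass_determinant(kd, kds)
    u_pid = kp * e + ki * z + kd * edot
    u_s = kps * e + kis * z + kds * edot
    return e, edot, u_pid, u_s


def simulate(
    cfg: ModelConfig,
    ic: SystemState = DEFAULT_INITIAL_STATE,
    opts: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the coupled system over [0, horizon].

    Deterministic: identical (cfg, ic, opts) yield bit-identical trajectories.
    Raises :class:`IntegrationFailureError` if the solver gives up or the
    state leaves the finite range.
    """
    opts = opts or SolverOptions()
    t_eval = opts.grid()
    sol = solve_ivp(
        _rhs_factory(cfg),
        (0.0, opts.horizon),
        ic.as_array(),
        method=opts.method,
        t_eval=t_eval,
        rtol=opts.rtol,
        atol=opts.atol,
        dense_output=False,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationFailureError(
            f"integration failed at t={t_fail:.6g}: {sol.message}", t_fail=t_fail
        )
    if not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.isfinite(sol.y).all(axis=0))
        t_fail = float(sol.t[bad])
        raise IntegrationFailureError(
            f"non-finite state encountered at t={t_fail:.6g}", t_fail=t_fail
        )

    e, edot, u_pid, u_s = _derived_signals(sol.t, sol.y, cfg)
    return Trajectory(
        t=sol.t.copy(),
        x1=sol.y[0], y1=sol.y[1], x2=sol.y[2], y2=sol.y[3], z=sol.y[4],
        e=e, edot=edot, u_pid=u_pid, u_s=u_s,
        config=cfg,
    )


def error_signal(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Return the synchronization error e(t) and its resolved rate de/dt."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    return traj.e, traj.edot
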