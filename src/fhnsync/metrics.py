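"""Synchronization-quality metrics computed from a sampled trajectory.

All metrics operate on the sampled synchronization error e(t) = x1 - x2:

* ``objective_j`` — the integrated squared error J = int_0^tau e^2 dt, the
  quantity minimized when tuning the supervisory gains;
* ``steady_state_error`` — mean |e| over a terminal window, quantifying how
  well the neurons lock after the transient;
* ``peak_error`` — max |e| over the whole horizon, the overshoot proxy;
* ``terminal_oscillation`` — standard deviation of e over the terminal
  window, quantifying residual oscillation about the locked state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "SyncMetrics",
    "objective_j",
    "steady_state_error",
    "terminal_oscillation",
    "compute_metrics",
    "DEFAULT_WINDOW_FRACTION",
]

#: Fraction of the horizon (taken from the end) over which steady-state
#: statistics are averaged.
DEFAULT_WINDOW_FRACTION = 0.2


@dataclass(frozen=True)
class SyncMetrics:
    steady_state_error: float
    peak_error: float
    terminal_oscillation: float
    objective_j: float

    def to_frame(self, run_id: str = "run") -> pd.DataFrame:
        return pd.DataFrame([{"run_id": run_id, **asdict(self)}])

    def to_csv(self, path, run_id: str = "run") -> None:
        self.to_frame(run_id).to_csv(path, index=False)


def objective_j(e: np.ndarray, t: np.ndarray, tau: float | None = None) -> float:
    """Integrated squared synchronization error J = int_0^tau e^2 dt.

    Trapezoidal quadrature on the sample grid; if tau falls between samples
    the integrand is linearly interpolated at tau.  tau defaults to the full
    sampled horizon.
    """
    e = np.asarray(e, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples to integrate")
    if tau is None:
        tau = float(t[-1])
    if tau > t[-1] or tau < t[0]:
        raise ValueError(f"tau={tau} outside the sampled range [{t[0]}, {t[-1]}]")
    mask = t <= tau
    tt = t[mask]
    ee = e[mask]
    if tt[-1] < tau:
        tt = np.append(tt, tau)
        ee = np.append(ee, np.interp(tau, t, e))
    return float(np.trapezoid(ee**2, tt))


def _terminal_window(t: np.ndarray, window_fraction: float) -> np.ndarray:
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    t = np.asarray(t, dtype=float)
    t_start = t[0] + (1.0 - window_fraction) * (t[-1] - t[0])
    mask = t >= t_start
    if not mask.any():
        raise ValueError("terminal window contains no samples")
    return mask


def steady_state_error(
    e: np.ndarray, t: np.ndarray, window_fraction: float = DEFAULT_WINDOW_FRACTION
) -> float:
    """Mean |e| over the final ``window_fraction`` of the horizon."""
    mask = _terminal_window(t, window_fraction)
    return float(np.mean(np.abs(np.asarray(e, dtype=float)[mask])))


def terminal_oscillation(
    e: np.ndarray, t: np.ndarray, window_fraction: float = DEFAULT_WINDOW_FRACTION
) -> float:
    """Standard deviation of e over the final ``window_fraction`` of the horizon."""
    mask = _terminal_window(t, window_fraction)
    return float(np.std(np.asarray(e, dtype=float)[mask]))


def compute_metrics(
    traj: Trajectory,
    tau: float | None = None,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> SyncMetrics:
    """Aggregate all synchronization metrics for one trajectory."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    return SyncMetrics(
        steady_state_error=steady_state_error(traj.e, traj.t, window_fraction),
        peak_error=float(np.max(np.abs(traj.e))),
        terminal_oscillation=terminal_oscillation(traj.e, traj.t, window_fraction),
        objective_j=objective_j(traj.e, traj.t, tau),
    )
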