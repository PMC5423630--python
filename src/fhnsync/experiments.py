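"""Scripted studies: natural-gain sweeps and PSO-tuned supervisory control.

The study parameters follow the reference two-neuron setup used throughout
the package: mismatched neurons (r1 = 10, r2 = 10.5, b1 = 1, b2 = 1.2) under
a shared sinusoidal stimulus (a = 0.1, omega = 0.8796).  Three sweeps probe
one natural coupling gain each while the other two are held small:

* proportional sweep kp in {0.1, 0.3, 0.6, 1} (ki = 1e-4, kd = 1e-5):
  stronger resistive coupling lowers the steady-state error;
* integral sweep ki in {1e-4, 0.3, 0.6, 1} (kp = 1, kd = 1e-5): inductive
  coupling drives the steady-state error toward zero;
* derivative sweep kd in {0.001, 0.04, 0.1, 0.3} (kp = ki = 0.01):
  capacitive coupling damps the residual oscillation.

The supervisory study starts from a deliberately deficient natural coupling
(all three gains 1e-4, recorded in the study output) under which the two
potentials stay incoherent, then tunes the supervisory PID gains with the
particle swarm optimizer to minimize J = int e^2 dt of the closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import DEFAULT_WINDOW_FRACTION, SyncMetrics, compute_metrics
from .model import (
    CouplingGains,
    ModelConfig,
    NeuronParams,
    SingularCouplingError,
    StimulusParams,
    SupervisoryGains,
    SystemState,
)
from .pso import OptimizationResult, SwarmConfig, optimize
from .simulate import (
    DEFAULT_INITIAL_STATE,
    IntegrationFailureError,
    SolverOptions,
    Trajectory,
    simulate,
)

__all__ = [
    "REFERENCE_NEURON1",
    "REFERENCE_NEURON2",
    "REFERENCE_STIMULUS",
    "DEFICIENT_COUPLING",
    "reference_config",
    "SweepSpec",
    "SweepResult",
    "default_sweep_spec",
    "run_sweep",
    "NoDeficiencyError",
    "SupervisoryStudyResult",
    "run_supervisory_study",
]

REFERENCE_NEURON1 = NeuronParams(r=10.0, b=1.0)
REFERENCE_NEURON2 = NeuronParams(r=10.5, b=1.2)
REFERENCE_STIMULUS = StimulusParams(a=0.1, omega=0.8796)

#: Natural coupling too weak to synchronize the mismatched neurons; the
#: starting point of the supervisory study.
DEFICIENT_COUPLING = CouplingGains(kp=1e-4, ki=1e-4, kd=1e-4)

#: Supervisory search box: symmetric in kp_s and ki_s so gains of either
#: sign are reachable; kd_s bounded below so the mass-matrix determinant
#: 1 + 2 kd + kd_s stays positive and the closed loop remains well posed.
SUPERVISORY_BOUNDS = ((-2.0, 2.0), (-2.0, 2.0), (-0.9, 2.0))

#: Finite penalty assigned to candidate gains whose closed loop blows up;
#: far above any J reachable by a bounded trajectory at these horizons.
_DIVERGENCE_PENALTY = 1e6

_SWEEP_GRIDS: dict[str, tuple[tuple[float, ...], CouplingGains]] = {
    "kp": ((0.1, 0.3, 0.6, 1.0), CouplingGains(kp=0.0, ki=1e-4, kd=1e-5)),
    "ki": ((1e-4, 0.3, 0.6, 1.0), CouplingGains(kp=1.0, ki=0.0, kd=1e-5)),
    "kd": ((0.001, 0.04, 0.1, 0.3), CouplingGains(kp=0.01, ki=0.01, kd=0.0)),
}


def reference_config(
    coupling: CouplingGains,
    supervisory: SupervisoryGains | None = None,
) -> ModelConfig:
    """Reference mismatched-neuron configuration with the given coupling."""
    return ModelConfig(
        neuron1=REFERENCE_NEURON1,
        neuron2=REFERENCE_NEURON2,
        stimulus=REFERENCE_STIMULUS,
        coupling=coupling,
        supervisory=supervisory or SupervisoryGains.zero(),
    )


@dataclass(frozen=True)
class SweepSpec:
    """One-gain sweep: vary ``gain`` over ``values``, others from ``fixed``."""

    gain: str  # one of kp, ki, kd
    values: tuple[float, ...]
    fixed: CouplingGains
    base: ModelConfig
    opts: SolverOptions = field(default_factory=SolverOptions)
    ic: SystemState = DEFAULT_INITIAL_STATE
    window_fraction: float = DEFAULT_WINDOW_FRACTION

    def __post_init__(self) -> None:
        if self.gain not in ("kp", "ki", "kd"):
            raise ValueError(f"gain must be one of kp/ki/kd, got {self.gain!r}")
        if len(self.values) == 0:
            raise ValueError("swept values must be non-empty")
        if len(set(self.values)) != len(self.values):
            raise ValueError("swept values must be distinct")

    def config_for(self, value: float) -> ModelConfig:
        gains = replace(self.fixed, **{self.gain: value})
        return self.base.with_coupling(gains)


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame  # one row per swept value, ordered by swept value
    trajectories: tuple[Trajectory, ...]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_sweep_spec(
    gain: str,
    opts: SolverOptions | None = None,
    ic: SystemState = DEFAULT_INITIAL_STATE,
) -> SweepSpec:
    """The reference sweep grid for one of the three natural gains."""
    if gain not in _SWEEP_GRIDS:
        raise ValueError(f"gain must be one of {sorted(_SWEEP_GRIDS)}, got {gain!r}")
    values, fixed = _SWEEP_GRIDS[gain]
    return SweepSpec(
        gain=gain,
        values=values,
        fixed=fixed,
        base=reference_config(fixed),
        opts=opts or SolverOptions(),
        ic=ic,
    )


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Simulate once per swept gain value under shared ICs and solver settings."""
    rows = []
    trajectories = []
    for value in sorted(spec.values):
        cfg = spec.config_for(value)
        try:
            traj = simulate(cfg, ic=spec.ic, opts=spec.opts)
        except Exception as err:
            raise RuntimeError(f"sweep failed at {spec.gain}={value}: {err}") from err
        m = compute_metrics(traj, window_fraction=spec.window_fraction)
        rows.append(
            {
                spec.gain: value,
                "steady_state_error": m.steady_state_error,
                "peak_error": m.peak_error,
                "terminal_oscillation": m.terminal_oscillation,
                "objective_j": m.objective_j,
            }
        )
        trajectories.append(traj)
    return SweepResult(spec=spec, table=pd.DataFrame(rows), trajectories=tuple(trajectories))


class NoDeficiencyError(RuntimeError):
    """The baseline is already synchronized; supervisory tuning is vacuous."""


@dataclass(frozen=True)
class SupervisoryStudyResult:
    baseline: Trajectory
    baseline_metrics: SyncMetrics
    optimization: OptimizationResult
    tuned: Trajectory
    tuned_metrics: SyncMetrics
    tuned_gains: SupervisoryGains

    @property
    def error_reduction(self) -> float:
        """tuned / baseline steady-state error ratio (small is good)."""
        return self.tuned_metrics.steady_state_error / self.baseline_metrics.steady_state_error

    def convergence_frame(self) -> pd.DataFrame:
        df = self.optimization.history.rename(
            columns={"x0": "kp_s", "x1": "ki_s", "x2": "kd_s"}
        )
        return df


def run_supervisory_study(
    cfg: ModelConfig | None = None,
    swarm: SwarmConfig | None = None,
    tau: float | None = None,
    opts: SolverOptions | None = None,
    ic: SystemState = DEFAULT_INITIAL_STATE,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    deficiency_threshold: float = 0.05,
) -> SupervisoryStudyResult:
    """Tune supervisory PID gains by PSO to rescue a weakly coupled pair.

    The objective evaluated per particle is J = int_0^tau e^2 dt of a full
    closed-loop simulation with the candidate supervisory gains.  Raises
    :class:`NoDeficiencyError` if the uncontrolled baseline already has a
    steady-state error below ``deficiency_threshold``.
    """
    cfg = cfg or reference_config(DEFICIENT_COUPLING)
    swarm = swarm or SwarmConfig(bounds=SUPERVISORY_BOUNDS)
    opts = opts or SolverOptions()

    baseline_cfg = cfg.with_supervisory(SupervisoryGains.zero())
    baseline = simulate(baseline_cfg, ic=ic, opts=opts)
    baseline_metrics = compute_metrics(baseline, tau=tau, window_fraction=window_fraction)
    if baseline_metrics.steady_state_error <= deficiency_threshold:
        raise NoDeficiencyError(
            f"baseline steady-state error {baseline_metrics.steady_state_error:.4g} "
            f"already below the deficiency threshold {deficiency_threshold}"
        )

    def objective(gains: np.ndarray) -> float:
        try:
            candidate = cfg.with_supervisory(
                SupervisoryGains(kp_s=float(gains[0]), ki_s=float(gains[1]), kd_s=float(gains[2]))
            )
            traj = simulate(candidate, ic=ic, opts=opts)
        except (IntegrationFailureError, SingularCouplingError):
            # unstable closed loop: worst finite score, keeps the swarm moving
            return _DIVERGENCE_PENALTY
        return compute_metrics(traj, tau=tau, window_fraction=window_fraction).objective_j

    result = optimize(objective, swarm)
    tuned_gains = SupervisoryGains(
        kp_s=float(result.gbest_position[0]),
        ki_s=float(result.gbest_position[1]),
        kd_s=float(result.gbest_position[2]),
    )
    tuned = simulate(cfg.with_supervisory(tuned_gains), ic=ic, opts=opts)
    tuned_metrics = compute_metrics(tuned, tau=tau, window_fraction=window_fraction)
    return SupervisoryStudyResult(
        baseline=baseline,
        baseline_metrics=baseline_metrics,
        optimization=result,
        tuned=tuned,
        tuned_metrics=tuned_metrics,
        tuned_gains=tuned_gains,
    )
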