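"""Two FitzHugh-Nagumo neurons coupled through an RLC medium.

The coupling medium between two electrically coupled neurons is modeled as a
parallel RLC circuit: the conduction current from one neuron to the other is
the sum of a resistive term ``g*e``, a capacitive term ``g_c*de/dt`` and an
inductive term ``g_l * int_0^t e dt``, where ``e = x1 - x2`` is the difference
of the activation potentials.  Collected, the three terms form a three-term
(PID) feedback law on the synchronization error, with ``kp = g``, ``ki = g_l``
and ``kd = g_c``.

Because the capacitive (derivative) term contains ``de/dt = dx1/dt - dx2/dt``,
the coupled equations define the state derivatives *implicitly*.  The system
is linear in ``(dx1/dt, dx2/dt)``, so :func:`resolve_derivatives` solves the
2x2 mass-matrix system in closed form instead of handing the problem to a DAE
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "StimulusParams",
    "CouplingGains",
    "SupervisoryGains",
    "SystemState",
    "StateDerivative",
    "CouplingCurrentBreakdown",
    "ModelConfig",
    "SingularCouplingError",
    "fhn_cubic",
    "stimulus_current",
    "coupling_breakdown",
    "pid_signal",
    "mass_determinant",
    "resolve_derivatives",
]

#: Mass-matrix determinants below this magnitude are treated as singular.
DET_THRESHOLD = 1e-12


class SingularCouplingError(ValueError):
    """The derivative-coupling gains make the mass matrix (near-)singular."""


def _require_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class NeuronParams:
    """FHN single-neuron coefficients.

    r   nonlinearity coefficient of the cubic activation term (dimensionless)
    b   recovery gain (dimensionless, non-negative)
    v   recovery leak coefficient (dimensionless); the coupled model uses
        v = 0, a nonzero leak is available for the standalone neuron form
    """

    r: float
    b: float
    v: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(r=self.r, b=self.b, v=self.v)
        if self.b < 0:
            raise ValueError(f"recovery gain b must be >= 0, got {self.b}")


@dataclass(frozen=True)
class StimulusParams:
    """Sinusoidal external stimulation current ``(a/omega) * cos(omega*t)``."""

    a: float
    omega: float

    def __post_init__(self) -> None:
        _require_finite(a=self.a, omega=self.omega)
        if self.omega == 0:
            raise ValueError("stimulus.omega must be nonzero (drive amplitude is a/omega)")


@dataclass(frozen=True)
class CouplingGains:
    """Natural coupling-medium strengths, written as PID gains.

    The resistive, inductive and capacitive strengths of the medium act as
    proportional, integral and derivative feedback on e = x1 - x2, so the
    gains are stored once under their controller names; ``g``, ``g_l`` and
    ``g_c`` are read-only aliases.
    """

    kp: float = 0.0
    ki: float = 0.0
    kd: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(kp=self.kp, ki=self.ki, kd=self.kd)

    @property
    def g(self) -> float:
        """Resistive conduction strength (alias of kp)."""
        return self.kp

    @property
    def g_l(self) -> float:
        """Inductive conduction strength (alias of ki)."""
        return self.ki

    @property
    def g_c(self) -> float:
        """Capacitive conduction strength (alias of kd)."""
        return self.kd


@dataclass(frozen=True)
class SupervisoryGains:
    """Supervisory PID gains added to neuron 2 to compensate weak coupling."""

    kp_s: float = 0.0
    ki_s: float = 0.0
    kd_s: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(kp_s=self.kp_s, ki_s=self.ki_s, kd_s=self.kd_s)

    # Alias view so the supervisory triple can be fed to pid_signal() like
    # any other three-term gain set.
    @property
    def kp(self) -> float:
        return self.kp_s

    @property
    def ki(self) -> float:
        return self.ki_s

    @property
    def kd(self) -> float:
        return self.kd_s

    @classmethod
    def zero(cls) -> "SupervisoryGains":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SystemState:
    """Augmented state (x1, y1, x2, y2, z).

    x1, x2  activation potentials; y1, y2 recovery variables; z accumulates
    the synchronization error (dz/dt = e, z(0) = 0), realizing the inductive
    coupling integral and the supervisory integral in one shared state.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    z: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(x1=self.x1, y1=self.y1, x2=self.x2, y2=self.y2, z=self.z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2, self.z], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        x1, y1, x2, y2, z = (float(v) for v in y)
        return cls(x1, y1, x2, y2, z)

    @property
    def e(self) -> float:
        """Synchronization error x1 - x2."""
        return self.x1 - self.x2


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of :class:`SystemState`, with the resolved error rate."""

    dx1: float
    dy1: float
    dx2: float
    dy2: float
    dz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dx1, self.dy1, self.dx2, self.dy2, self.dz], dtype=float)

    @property
    def edot(self) -> float:
        return self.dx1 - self.dx2


@dataclass(frozen=True)
class CouplingCurrentBreakdown:
    """Conduction current split into resistive, capacitive, inductive parts."""

    i_r: float
    i_c: float
    i_l: float

    @property
    def total(self) -> float:
        return self.i_r + self.i_c + self.i_l


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of the coupled two-neuron system."""

    neuron1: NeuronParams
    neuron2: NeuronParams
    stimulus: StimulusParams
    coupling: CouplingGains
    supervisory: SupervisoryGains = field(default_factory=SupervisoryGains.zero)

    def __post_init__(self) -> None:
        det = mass_determinant(self.coupling.kd, self.supervisory.kd_s)
        if abs(det) <= DET_THRESHOLD:
            raise SingularCouplingError(
                f"mass matrix singular: 1 + 2*kd + kd_s = {det:.3e} "
                f"(kd={self.coupling.kd}, kd_s={self.supervisory.kd_s})"
            )

    def with_supervisory(self, gains: SupervisoryGains) -> "ModelConfig":
        return ModelConfig(self.neuron1, self.neuron2, self.stimulus, self.coupling, gains)

    def with_coupling(self, gains: CouplingGains) -> "ModelConfig":
        return ModelConfig(self.neuron1, self.neuron2, self.stimulus, gains, self.supervisory)


def fhn_cubic(x: float, r: float):
    """Cubic activation nonlinearity f(x) = x (x - 1) (1 - r x).

    Roots at x = 0, x = 1 and x = 1/r.  Accepts numpy arrays in ``x`` for
    vectorized trajectory post-processing.
    """
    if np.isscalar(x) and not math.isfinite(x):
        raise ValueError(f"activation potential must be finite, got {x!r}")
    if not math.isfinite(r):
        raise ValueError(f"nonlinearity coefficient must be finite, got {r!r}")
    return x * (x - 1.0) * (1.0 - r * x)


def stimulus_current(t, stim: StimulusParams):
    """External stimulation current (a/omega) * cos(omega * t)."""
    if stim.omega == 0:
        raise ValueError("stimulus.omega must be nonzero")
    return (stim.a / stim.omega) * np.cos(stim.omega * t)


def coupling_breakdown(e: float, z: float, edot: float, gains) -> CouplingCurrentBreakdown:
    """Split the conduction current kp*e + ki*z + kd*edot into its components."""
    _require_finite(e=e, z=z, edot=edot)
    return CouplingCurrentBreakdown(i_r=gains.kp * e, i_c=gains.kd * edot, i_l=gains.ki * z)


def pid_signal(e: float, z: float, edot: float, gains) -> float:
    """Three-term control current kp*e + ki*z + kd*edot.

    ``gains`` is any object with kp/ki/kd attributes — the natural coupling
    triple or the supervisory triple.
    """
    return coupling_breakdown(e, z, edot, gains).total


def mass_determinant(kd: float, kd_s: float = 0.0) -> float:
    """det of the 2x2 mass matrix [[1+kd, -kd], [-(kd+kd_s), 1+kd+kd_s]]."""
    return 1.0 + 2.0 * kd + kd_s


def resolve_derivatives(state: SystemState, t: float, cfg: ModelConfig) -> StateDerivative:
    """Evaluate the coupled system's explicit state derivative at (state, t).

    The activation equations are

        dx1/dt = f1(x1) - y1 + I_s(t) - u_pid
        dx2/dt = f2(x2) - y2 + I_s(t) + u_pid + u_s

    with u_pid and u_s both containing kd-weighted de/dt terms, so dx1/dt and
    dx2/dt appear on both sides.  Moving the derivative terms to the left
    gives M (dx1, dx2)^T = (F1, F2)^T with

        M = [[1+kd, -kd], [-(kd+kd_s), 1+kd+kd_s]],  det M = 1 + 2 kd + kd_s.

    Subtracting the rows yields de/dt = (F1 - F2)/det directly, after which
    dx1/dt = F1 - kd*de/dt and dx2/dt = dx1/dt - de/dt.  This back-substituted
    form is exact and, when F1 == F2, yields de/dt == 0 bitwise so perfectly
    symmetric neurons never desynchronize through rounding.
    """
    kp, ki, kd = cfg.coupling.kp, cfg.coupling.ki, cfg.coupling.kd
    kps, kis, kds = cfg.supervisory.kp_s, cfg.supervisory.ki_s, cfg.supervisory.kd_s

    det = mass_determinant(kd, kds)
    if abs(det) <= DET_THRESHOLD:
        raise SingularCouplingError(
            f"mass matrix singular: 1 + 2*kd + kd_s = {det:.3e} (kd={kd}, kd_s={kds})"
        )

    e = state.x1 - state.x2
    s = stimulus_current(t, cfg.stimulus)
    f1 = fhn_cubic(state.x1, cfg.neuron1.r)
    f2 = fhn_cubic(state.x2, cfg.neuron2.r)

    # Right-hand sides with the derivative-coupling terms moved to the left.
    F1 = f1 - state.y1 + s - kp * e - ki * state.z
    F2 = f2 - state.y2 + s + (kp + kps) * e + (ki + kis) * state.z

    edot = (F1 - F2) / det
    dx1 = F1 - kd * edot
    dx2 = dx1 - edot

    dy1 = cfg.neuron1.b * state.x1 + cfg.neuron1.v * state.y1
    dy2 = cfg.neuron2.b * state.x2 + cfg.neuron2.v * state.y2

    return StateDerivative(dx1=dx1, dy1=dy1, dx2=dx2, dy2=dy2, dz=e)
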