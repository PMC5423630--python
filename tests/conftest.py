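import numpy as np
import pytest

from fhnsync import (
    CouplingGains,
    ModelConfig,
    NeuronParams,
    StimulusParams,
    SupervisoryGains,
    SystemState,
    resolve_derivatives,
)


@pytest.fixture
def reference_neurons():
    return NeuronParams(r=10.0, b=1.0), NeuronParams(r=10.5, b=1.2)


@pytest.fixture
def reference_stimulus():
    return StimulusParams(a=0.1, omega=0.8796)


@pytest.fixture
def make_config(reference_neurons, reference_stimulus):
    """Factory for the mismatched reference pair with arbitrary gains."""
    n1, n2 = reference_neurons

    def _make(kp=0.0, ki=0.0, kd=0.0, kp_s=0.0, ki_s=0.0, kd_s=0.0):
        return ModelConfig(
            neuron1=n1,
            neuron2=n2,
            stimulus=reference_stimulus,
            coupling=CouplingGains(kp=kp, ki=ki, kd=kd),
            supervisory=SupervisoryGains(kp_s=kp_s, ki_s=ki_s, kd_s=kd_s),
        )

    return _make


def fixed_point_derivatives(state, t, cfg, tol=1e-14, max_iter=500):
    """Independent oracle for the implicitly coupled activation derivatives.

    Iterates the raw coupled equations

        dx1 <- F1 - kd*(dx1 - dx2)
        dx2 <- F2 + (kd + kd_s)*(dx1 - dx2)

    to a fixed point, never forming the mass matrix.  Converges whenever
    |2 kd + kd_s| < 1.
    """
    from fhnsync.model import fhn_cubic, stimulus_current

    kp, ki, kd = cfg.coupling.kp, cfg.coupling.ki, cfg.coupling.kd
    kps, kis, kds = cfg.supervisory.kp_s, cfg.supervisory.ki_s, cfg.supervisory.kd_s
    e = state.x1 - state.x2
    s = float(stimulus_current(t, cfg.stimulus))
    F1 = fhn_cubic(state.x1, cfg.neuron1.r) - state.y1 + s - kp * e - ki * state.z
    F2 = fhn_cubic(state.x2, cfg.neuron2.r) - state.y2 + s + (kp + kps) * e + (ki + kis) * state.z
    dx1, dx2 = F1, F2
    for _ in range(max_iter):
        edot = dx1 - dx2
        new1 = F1 - kd * edot
        new2 = F2 + (kd + kds) * edot
        if abs(new1 - dx1) < tol and abs(new2 - dx2) < tol:
            dx1, dx2 = new1, new2
            break
        dx1, dx2 = new1, new2
    return dx1, dx2


def implicit_residuals(state, t, cfg):
    """Residuals of the raw implicit activation equations at the resolved point."""
    from fhnsync.model import fhn_cubic, stimulus_current

    d = resolve_derivatives(state, t, cfg)
    kp, ki, kd = cfg.coupling.kp, cfg.coupling.ki, cfg.coupling.kd
    kps, kis, kds = cfg.supervisory.kp_s, cfg.supervisory.ki_s, cfg.supervisory.kd_s
    e = state.x1 - state.x2
    edot = d.dx1 - d.dx2
    s = float(stimulus_current(t, cfg.stimulus))
    u_pid = kp * e + ki * state.z + kd * edot
    u_s = kps * e + kis * state.z + kds * edot
    r1 = d.dx1 - (fhn_cubic(state.x1, cfg.neuron1.r) - state.y1 + s - u_pid)
    r2 = d.dx2 - (fhn_cubic(state.x2, cfg.neuron2.r) - state.y2 + s + u_pid + u_s)
    return r1, r2


def random_state(rng, scale=2.0):
    x1, y1, x2, y2, z = rng.uniform(-scale, scale, size=5)
    return SystemState(x1=x1, y1=y1, x2=x2, y2=y2, z=z)
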