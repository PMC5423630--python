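"""Unit and property tests for the coupled-model layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fhnsync import (
    CouplingGains,
    SingularCouplingError,
    SupervisoryGains,
    SystemState,
    coupling_breakdown,
    fhn_cubic,
    mass_determinant,
    pid_signal,
    resolve_derivatives,
    stimulus_current,
)
from fhnsync.model import StimulusParams, NeuronParams

from conftest import fixed_point_derivatives, implicit_residuals, random_state

finite_floats = st.floats(-5, 5, allow_nan=False)


class TestFhnCubic:
    @pytest.mark.parametrize(
        "x, r, expected",
        [
            (0.0, 10.0, 0.0),
            (1.0, 10.0, 0.0),
            (0.5, 10.0, 1.0),  # 0.5 * (-0.5) * (1 - 5) = 1
            (0.1, 10.0, 0.0),  # root at x = 1/r
        ],
    )
    def test_known_values(self, x, r, expected):
        assert fhn_cubic(x, r) == pytest.approx(expected, abs=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            fhn_cubic(float("nan"), 10.0)
        with pytest.raises(ValueError):
            fhn_cubic(0.5, float("inf"))


class TestStimulus:
    def test_peak_at_t_zero(self):
        stim = StimulusParams(a=0.1, omega=0.8796)
        assert stimulus_current(0.0, stim) == pytest.approx(0.1 / 0.8796)
        assert stimulus_current(0.0, stim) == pytest.approx(0.113688, abs=1e-6)

    def test_zero_amplitude(self):
        stim = StimulusParams(a=0.0, omega=1.3)
        for t in (0.0, 1.0, 17.2):
            assert stimulus_current(t, stim) == 0.0

    def test_half_period_sign_flip(self):
        stim = StimulusParams(a=0.4, omega=2.0)
        assert stimulus_current(math.pi / 2.0, stim) == pytest.approx(-0.2)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            StimulusParams(a=0.1, omega=0.0)


class TestPidSignal:
    @pytest.mark.parametrize(
        "e, z, edot, gains, expected",
        [
            (0.0, 0.0, 0.0, CouplingGains(kp=0.6, ki=1.0, kd=0.3), 0.0),
            (1.0, 0.0, 0.0, CouplingGains(kp=0.6, ki=1.0, kd=0.3), 0.6),
            (0.2, 1.5, -0.1, CouplingGains(kp=1.0, ki=0.3, kd=0.04), 0.646),
        ],
    )
    def test_known_values(self, e, z, edot, gains, expected):
        assert pid_signal(e, z, edot, gains) == pytest.approx(expected)

    def test_supervisory_gains_accepted(self):
        gains = SupervisoryGains(kp_s=0.9, ki_s=0.7, kd_s=-0.1)
        assert pid_signal(1.0, 2.0, 3.0, gains) == pytest.approx(0.9 + 1.4 - 0.3)

    @given(e=finite_floats, z=finite_floats, edot=finite_floats,
           kp=finite_floats, ki=finite_floats, kd=finite_floats)
    @settings(max_examples=100, deadline=None)
    def test_breakdown_sums_to_total(self, e, z, edot, kp, ki, kd):
        gains = CouplingGains(kp=kp, ki=ki, kd=kd)
        bk = coupling_breakdown(e, z, edot, gains)
        assert bk.total == bk.i_r + bk.i_c + bk.i_l
        assert bk.total == pid_signal(e, z, edot, gains)

    def test_resistive_only_reduction(self):
        # with ki = kd = 0 the conduction current is the conventional g*(x1-x2)
        gains = CouplingGains(kp=0.7, ki=0.0, kd=0.0)
        x1, x2 = 1.3, 0.4
        assert pid_signal(x1 - x2, 5.0, -2.0, gains) == pytest.approx(0.7 * (x1 - x2))


class TestMassMatrix:
    @given(kd=st.floats(-0.45, 0.45), kd_s=st.floats(-0.45, 0.45))
    @settings(max_examples=100, deadline=None)
    def test_determinant_matches_generic_2x2(self, kd, kd_s):
        M = np.array([[1 + kd, -kd], [-(kd + kd_s), 1 + kd + kd_s]])
        assert mass_determinant(kd, kd_s) == pytest.approx(np.linalg.det(M), rel=1e-12, abs=1e-12)

    def test_singular_coupling_raises_with_gains_named(self, make_config):
        with pytest.raises(SingularCouplingError) as excinfo:
            make_config(kd=-0.5, kd_s=0.0)
        assert "kd" in str(excinfo.value)


class TestResolveDerivatives:
    def test_symmetric_neurons_have_equal_derivatives(self, reference_stimulus):
        from fhnsync import ModelConfig

        n = NeuronParams(r=10.0, b=1.0)
        cfg = ModelConfig(
            neuron1=n, neuron2=n, stimulus=reference_stimulus,
            coupling=CouplingGains(kp=0.6, ki=0.3, kd=0.2),
        )
        state = SystemState(x1=0.4, y1=-0.2, x2=0.4, y2=-0.2, z=0.0)
        d = resolve_derivatives(state, 1.7, cfg)
        assert d.dx1 == d.dx2  # bitwise: all coupling terms vanish
        assert d.edot == 0.0
        # matches the uncoupled single-neuron rate
        expected = fhn_cubic(0.4, 10.0) + 0.2 + float(stimulus_current(1.7, reference_stimulus))
        assert d.dx1 == pytest.approx(expected, rel=1e-14)

    def test_reduces_to_explicit_form_when_kd_zero(self, make_config):
        cfg = make_config(kp=0.5, ki=0.2, kd=0.0)
        state = SystemState(x1=0.3, y1=0.1, x2=-0.2, y2=0.05, z=0.4)
        d = resolve_derivatives(state, 2.0, cfg)
        e = state.x1 - state.x2
        s = float(stimulus_current(2.0, cfg.stimulus))
        u = 0.5 * e + 0.2 * state.z
        assert d.dx1 == pytest.approx(fhn_cubic(0.3, 10.0) - 0.1 + s - u, rel=1e-12)
        assert d.dx2 == pytest.approx(fhn_cubic(-0.2, 10.5) - 0.05 + s + u, rel=1e-12)
        assert d.dy1 == pytest.approx(1.0 * 0.3)
        assert d.dy2 == pytest.approx(1.2 * -0.2)
        assert d.dz == pytest.approx(e)

    def test_agrees_with_fixed_point_oracle(self, make_config):
        cfg = make_config(kp=0.6, ki=0.3, kd=0.3, kp_s=0.2, ki_s=0.1, kd_s=0.1)
        rng = np.random.default_rng(42)
        for _ in range(50):
            state = random_state(rng)
            t = rng.uniform(0, 50)
            d = resolve_derivatives(state, t, cfg)
            ox1, ox2 = fixed_point_derivatives(state, t, cfg)
            scale = max(1.0, abs(ox1), abs(ox2))
            assert abs(d.dx1 - ox1) / scale < 1e-9
            assert abs(d.dx2 - ox2) / scale < 1e-9

    def test_implicit_residuals_small(self, make_config):
        rng = np.random.default_rng(7)
        for _ in range(200):
            kd, kd_s = rng.uniform(-0.4, 0.4, size=2)
            if abs(mass_determinant(kd, kd_s)) < 1e-3:
                continue
            cfg = make_config(
                kp=rng.uniform(-2, 2), ki=rng.uniform(-2, 2), kd=kd,
                kp_s=rng.uniform(-1, 1), ki_s=rng.uniform(-1, 1), kd_s=kd_s,
            )
            state = random_state(rng)
            r1, r2 = implicit_residuals(state, rng.uniform(0, 100), cfg)
            assert abs(r1) < 1e-9 and abs(r2) < 1e-9

    @given(
        kp=st.floats(-2, 2), ki=st.floats(-2, 2), kd=st.floats(-0.4, 0.4),
        x1=finite_floats, y1=finite_floats, x2=finite_floats, y2=finite_floats,
        z=finite_floats, t=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_sum_cancellation_invariant(self, kp, ki, kd, x1, y1, x2, y2, z, t):
        """With u_s off the coupling current enters with opposite signs, so
        the sum of activation rates is independent of all coupling gains."""
        from fhnsync import ModelConfig

        def cfg(**gains):
            return ModelConfig(
                neuron1=NeuronParams(r=10.0, b=1.0),
                neuron2=NeuronParams(r=10.5, b=1.2),
                stimulus=StimulusParams(a=0.1, omega=0.8796),
                coupling=CouplingGains(**gains),
            )

        state = SystemState(x1=x1, y1=y1, x2=x2, y2=y2, z=z)
        coupled = resolve_derivatives(state, t, cfg(kp=kp, ki=ki, kd=kd))
        uncoupled = resolve_derivatives(state, t, cfg())
        lhs = coupled.dx1 + coupled.dx2
        rhs = uncoupled.dx1 + uncoupled.dx2
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)


class TestTypeValidation:
    def test_negative_recovery_gain_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(r=10.0, b=-0.1)

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            SystemState(x1=float("nan"), y1=0, x2=0, y2=0)

    def test_gain_aliases(self):
        g = CouplingGains(kp=0.3, ki=0.2, kd=0.1)
        assert (g.g, g.g_l, g.g_c) == (0.3, 0.2, 0.1)
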