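"""Three-element Windkessel: circuit limits, integrators, discretisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wkloop as wk
from wkloop.windkessel import (
    WindkesselState,
    discretize_admittance,
    input_impedance,
    step_closed,
    step_open,
    time_constant,
)

GPA = 1e9
PM3 = 1e-12


@pytest.fixture(scope="module")
def normo():
    return wk.get_preset("normotensive")


class TestImpedance:
    def test_dc_limit_is_series_sum(self, normo):
        assert input_impedance(normo, 0.0) == pytest.approx(normo.Rp
                                                            + normo.Zc)

    def test_dc_value_normotensive(self, normo):
        assert input_impedance(normo, 0.0) / GPA == pytest.approx(15.0)

    def test_high_frequency_limit_is_Zc(self, normo):
        z = input_impedance(normo, 1j * 1e9)
        assert abs(z - normo.Zc) < 1e-3 * normo.Zc


class TestTimeConstant:
    def test_normotensive(self, normo):
        assert time_constant(normo) == pytest.approx(0.464)

    def test_hypertensive(self):
        assert time_constant(wk.get_preset("hypertensive")) == pytest.approx(
            21.4 * 15 * 1e-3)

    def test_linearity_in_Rp(self, normo):
        doubled = wk.WindkesselParams(Rp=2 * normo.Rp, C=normo.C,
                                      Zc=normo.Zc)
        assert time_constant(doubled) == pytest.approx(2 * time_constant(normo))


class TestClosedValveDecay:
    def test_exact_exponential_over_one_tau(self, normo):
        """After elapsed Rp*C the exact integrator lands on Pp0/e."""
        dt = 5e-5
        tau = normo.tau
        n = int(round(tau / dt))
        state = WindkesselState.closed(10e3)
        for _ in range(n):
            state = step_closed(state, normo, dt)
        expected = 10e3 * math.exp(-n * dt / tau)
        assert state.Pp == pytest.approx(expected, rel=1e-12)
        assert state.Pp == pytest.approx(10e3 / math.e, rel=1e-6)

    def test_semigroup_property(self, normo):
        s1 = step_closed(WindkesselState.closed(8e3), normo, 0.02)
        s2 = step_closed(step_closed(WindkesselState.closed(8e3), normo, 0.01),
                         normo, 0.01)
        assert s1.Pp == pytest.approx(s2.Pp, rel=1e-15)

    def test_trapezoidal_matches_exact_closely(self, normo):
        dt = 5e-5
        n = int(round(normo.tau / dt))
        se = st_ = WindkesselState.closed(10e3)
        for _ in range(n):
            se = step_closed(se, normo, dt)
            st_ = step_closed(st_, normo, dt, method="trapezoidal")
        assert st_.Pp == pytest.approx(se.Pp, rel=1e-4)

    def test_invalid_step(self, normo):
        with pytest.raises(wk.InvalidStepError):
            step_closed(WindkesselState.closed(1e3), normo, 0.0)


class TestOpenValve:
    def test_instantaneous_flow(self, normo):
        """Q = (P - Pp)/Zc: 2 kPa across 0.5 GPa.s/m3 gives 4 uL/s x 10^3."""
        state = WindkesselState(Pp=10e3, Pa=10e3, Q=0.0, valve_open=True)
        new = step_open(state, 12e3, normo, 1e-9)  # tiny dt: algebraic limit
        assert new.Q == pytest.approx((12e3 - 10e3) / normo.Zc, rel=1e-6)
        assert new.Q == pytest.approx(4.0e-6, rel=1e-4)

    def test_zero_gradient_zero_flow(self, normo):
        state = WindkesselState(Pp=10e3, Pa=10e3, Q=0.0, valve_open=True)
        new = step_open(state, 10e3, normo, 1e-9)
        assert new.Q == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_divider(self, normo):
        """Constant P held >> Rp*C: Q -> P/(Rp+Zc), Pp -> P*Rp/(Rp+Zc)."""
        P = 12e3
        dt = 5e-5
        state = WindkesselState(Pp=0.0, Pa=0.0, Q=0.0, valve_open=True)
        n = int(10 * normo.tau / dt)
        for _ in range(n):
            state = step_open(state, P, normo, dt)
        assert state.Q == pytest.approx(P / (normo.Rp + normo.Zc), rel=1e-4)
        assert state.Pp == pytest.approx(P * normo.Rp / (normo.Rp + normo.Zc),
                                         rel=1e-4)

    def test_pa_relation(self, normo):
        state = WindkesselState(Pp=9e3, Pa=9e3, Q=0.0, valve_open=True)
        new = step_open(state, 11e3, normo, 5e-5)
        assert new.Pa == pytest.approx(new.Pp + new.Q * normo.Zc, rel=1e-14)


class TestDiscreteAdmittance:
    def test_dc_gain(self, normo):
        da = discretize_admittance(normo, 5e-5)
        assert da.dc_gain == pytest.approx(1.0 / (normo.Rp + normo.Zc),
                                           rel=1e-12)

    def test_zero_input_zero_output(self, normo):
        da = discretize_admittance(normo, 5e-5)
        assert np.all(da.filter(np.zeros(100)) == 0.0)

    def test_constant_pressure_converges_to_dc_flow(self, normo):
        da = discretize_admittance(normo, 5e-5)
        P = 10e3
        n = int(10 * normo.tau / 5e-5)
        Q = da.filter(np.full(n, P))
        assert Q[-1] == pytest.approx(P / (normo.Rp + normo.Zc), rel=1e-4)

    def test_matches_state_space_on_smooth_trace(self, normo):
        """Tustin filter and trapezoidal state-space stepping agree on a
        physiological (smooth) open-valve pressure trace."""
        dt = 5e-5
        n = 4000
        t = np.arange(n) * dt
        P = 10e3 * np.sin(np.pi * t / t[-1]) ** 2  # smooth pulse, P(0)=0
        da = discretize_admittance(normo, dt)
        Qf = da.filter(P)
        state = WindkesselState(Pp=0.0, Pa=0.0, Q=0.0, valve_open=True)
        Qs = np.empty(n)
        Qs[0] = (P[0] - state.Pp) / normo.Zc
        for i in range(n - 1):
            # drive each step with the midpoint pressure (trapezoidal input)
            state = step_open(state, 0.5 * (P[i] + P[i + 1]), normo, dt)
            Qs[i + 1] = (P[i + 1] - state.Pp) / normo.Zc
        scale = np.max(np.abs(Qs))
        assert np.max(np.abs(Qf - Qs)) / scale < 1e-3

    @settings(deadline=None, max_examples=40)
    @given(
        Rp=st.floats(min_value=1.0, max_value=2000.0),
        C=st.floats(min_value=1.0, max_value=100.0),
        Zc=st.floats(min_value=0.05, max_value=20.0),
        dt_us=st.floats(min_value=5.0, max_value=1000.0),
    )
    def test_poles_inside_unit_circle(self, Rp, C, Zc, dt_us):
        params = wk.WindkesselParams(Rp=Rp * GPA, C=C * PM3, Zc=Zc * GPA)
        da = discretize_admittance(params, dt_us * 1e-6)
        assert np.all(np.abs(da.poles()) < 1.0)
        assert da.a[0] == pytest.approx(1.0)


class TestParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            wk.WindkesselParams(Rp=-1.0, C=1e-12, Zc=1e9)

    def test_zc_above_rp_warns_not_raises(self):
        with pytest.warns(UserWarning):
            wk.WindkesselParams(Rp=1e9, C=1e-12, Zc=2e9)

    def test_literature_unit_conversion(self):
        p = wk.WindkesselParams.from_literature_units(14.5, 32.0, 0.5)
        assert p.Rp == 14.5e9 and p.C == 32e-12 and p.Zc == 0.5e9


def test_small_Zc_recovers_two_element_behaviour(normo):
    """With Zc << Rp the series element vanishes: aortic pressure tracks
    peripheral pressure to within Zc*Q, a small fraction of Pp."""
    params = wk.WindkesselParams(Rp=normo.Rp, C=normo.C, Zc=1e-3 * normo.Rp)
    P, dt = 10e3, 5e-5
    state = WindkesselState(Pp=5e3, Pa=5e3, Q=0.0, valve_open=True)
    for _ in range(int(5 * normo.tau / dt)):
        state = step_open(state, P, params, dt)
    assert state.Pa - state.Pp == pytest.approx(state.Q * params.Zc,
                                                rel=1e-12)
    assert abs(state.Pa - state.Pp) < 2e-3 * state.Pp
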