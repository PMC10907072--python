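"""Unit and property tests for the six-compartment circulation core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvloop.core_model import (
    COMPARTMENTS,
    SEGMENTS,
    CirculationParameters,
    InvalidParameterError,
    PressureSourceError,
    SystemState,
    passive_pressure,
    reference_solution,
    run_cycles,
    segment_flow,
    step_fixed,
    system_pressures,
    volume_derivatives,
)
from cvloop.muscle_models import ElastanceVentricle, TwitchActivation


def zero_source(t, v):
    return 0.0


# ---------------------------------------------------------------------------
# constitutive relations
# ---------------------------------------------------------------------------

class TestPassivePressure:
    @pytest.mark.parametrize(
        "v, vu, c, expected",
        [
            (5e-6, 5e-6, 1.7e-9, 0.0),               # at unstressed volume
            (5e-6 + 1.7e-6, 5e-6, 1.7e-9, 1000.0),   # 1.7 mL over, C_VC
            (3e-6, 5e-6, 1.7e-9, 0.0),               # below unstressed: clamped
        ],
    )
    def test_values(self, v, vu, c, expected):
        assert passive_pressure(v, vu, c) == pytest.approx(expected, abs=1e-9)

    def test_rejects_nonpositive_compliance(self):
        with pytest.raises(InvalidParameterError):
            passive_pressure(1e-6, 0.0, 0.0)

    @given(
        st.floats(0, 1e-5), st.floats(0, 1e-5),
        st.floats(1e-12, 1e-8),
    )
    def test_never_negative(self, v, vu, c):
        assert passive_pressure(v, vu, c) >= 0.0


class TestSegmentFlow:
    def test_zero_gradient(self):
        assert segment_flow(1234.0, 1234.0, 5e9) == 0.0

    def test_aortic_valve_example(self):
        # 8 kPa across the 5 GPa·s·m^-3 aortic valve
        q = segment_flow(10e3, 2e3, 5e9, is_valve=True)
        assert q == pytest.approx(1.6e-6, rel=1e-12)

    def test_valve_blocks_reverse_flow(self):
        assert segment_flow(2e3, 10e3, 5e9, is_valve=True) == 0.0

    def test_nonvalve_allows_reverse_flow(self):
        assert segment_flow(2e3, 10e3, 5e9, is_valve=False) < 0.0

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(InvalidParameterError):
            segment_flow(1.0, 0.0, 0.0)


class TestVolumeDerivatives:
    def test_all_zero(self):
        assert np.all(volume_derivatives([0.0] * 6) == 0.0)

    def test_single_mitral_flow(self):
        # Q_MT fills LV from PU
        dv = volume_derivatives([0, 0, 0, 0, 0, 1e-6])
        assert dv[COMPARTMENTS.index("LV")] == pytest.approx(1e-6)
        assert dv[COMPARTMENTS.index("PU")] == pytest.approx(-1e-6)
        assert np.count_nonzero(dv) == 2

    @given(st.lists(st.floats(-1e-5, 1e-5), min_size=6, max_size=6))
    def test_rates_sum_to_zero(self, flows):
        assert volume_derivatives(flows).sum() == pytest.approx(0.0, abs=1e-18)


class TestSystemPressures:
    def test_rv_is_elastance_ratio_of_lv(self, params):
        state = params.initial_state()
        P = system_pressures(state, params, lambda t, v: 10e3)
        # 10 kPa x (40/170)
        assert P[COMPARTMENTS.index("RV")] == pytest.approx(2352.94, rel=1e-4)

    def test_zero_lv_gives_zero_rv(self, params):
        state = params.initial_state()
        P = system_pressures(state, params, zero_source)
        assert P[COMPARTMENTS.index("RV")] == 0.0

    def test_all_unstressed_all_zero(self, params):
        state = SystemState(t=0.0, V=tuple(params.unstressed_split))
        P = system_pressures(state, params, zero_source)
        assert np.all(P == 0.0)

    def test_nonfinite_source_names_time(self, params):
        state = params.initial_state()
        with pytest.raises(PressureSourceError, match="t=0.0"):
            system_pressures(state, params, lambda t, v: float("nan"))


class TestParameterValidation:
    def test_volume_partition_enforced(self):
        with pytest.raises(InvalidParameterError):
            CirculationParameters(V_t=24e-6, V_s=4e-6, V_u=21e-6)

    def test_unstressed_split_sums_to_vu(self, params):
        assert sum(params.unstressed_split) == pytest.approx(params.V_u, rel=1e-12)
        assert params.unstressed_split[0] == 0.0  # ventricles carry none
        assert params.unstressed_split[3] == 0.0

    def test_negative_resistance_rejected(self):
        with pytest.raises(InvalidParameterError):
            CirculationParameters(R_SYS=-1.0)

    def test_initial_state_conserves_total(self, params):
        assert params.initial_state().total_volume == pytest.approx(
            params.V_t, rel=1e-12
        )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class TestStepFixed:
    def test_zero_flows_only_advance_time(self, params):
        state = SystemState(t=0.0, V=tuple(params.unstressed_split))
        out = step_fixed(state, 5e-5, params, zero_source)
        assert out.t == pytest.approx(5e-5)
        assert out.V == state.V

    def test_conserves_total_volume(self, params):
        state = params.initial_state()
        for _ in range(100):
            state = step_fixed(state, 5e-5, params, lambda t, v: 5e3 * math.sin(t))
        assert state.total_volume == pytest.approx(params.V_t, rel=1e-12)

    def test_rejects_bad_dt(self, params):
        with pytest.raises(InvalidParameterError):
            step_fixed(params.initial_state(), 0.0, params, zero_source)


def _rc_pair_params():
    """Reduce the ring to a single R (R_SYS) joining the AO and VC
    compartments: all valves made impassable by enormous resistance."""
    return CirculationParameters(
        R_TC=1e30, R_PV=1e30, R_MT=1e30, R_AV=1e30
    )


class TestRCSubCircuit:
    """Two compartments joined by one resistor relax exponentially with
    time constant R·C1·C2/(C1+C2) to the equal-pressure partition."""

    def setup_method(self):
        self.p = _rc_pair_params()
        u = self.p.unstressed_split
        self.q10, self.q20 = 2.0e-6, 0.5e-6  # initial stressed volumes
        self.V0 = (0.0, u[1] + self.q10, u[2] + self.q20, 0.0, u[4], u[5])
        C1, C2 = self.p.C_AO, self.p.C_VC
        self.tau = self.p.R_SYS * C1 * C2 / (C1 + C2)
        qt = self.q10 + self.q20
        self.q1_inf = qt * C1 / (C1 + C2)

    def closed_form(self, t):
        return self.q1_inf + (self.q10 - self.q1_inf) * np.exp(-t / self.tau)

    def test_reference_matches_closed_form(self):
        t_eval = np.linspace(0.0, 2.0, 101)
        ref = reference_solution(
            SystemState(t=0.0, V=self.V0), self.p, zero_source, 2.0, t_eval=t_eval
        )
        q1 = ref.V[:, 1] - self.p.unstressed_split[1]
        assert np.max(np.abs(q1 - self.closed_form(t_eval))) / self.q10 < 1e-6

    def test_fixed_step_matches_closed_form(self):
        rec = run_cycles(
            SystemState(t=0.0, V=self.V0), self.p, zero_source,
            n_cycles=4, period=0.5, dt=1e-4, record="all",
            stop_at_steady_state=False,
        )
        q1 = rec.V[:, 1] - self.p.unstressed_split[1]
        err = np.max(np.abs(q1 - self.closed_form(rec.t))) / self.q10
        # explicit Euler at dt=1e-4 on tau~5.5 s: error O(dt/tau)
        assert err < 1e-4


class TestEulerConvergence:
    def test_observed_order_is_one(self, params):
        """Error against the adaptive reference halves with dt (order 1)."""
        act = TwitchActivation()
        lv = ElastanceVentricle(E_ES=params.E_ESLV, activation=act)
        rv = ElastanceVentricle(E_ES=params.E_ESRV, activation=act)
        s0 = params.initial_state()
        t_end = 0.5
        ref = reference_solution(
            s0, params, lv, t_end,
            rv_pressure_source=rv.rv_source(), t_eval=np.array([t_end]),
        )
        errs = []
        for dt in (4e-4, 2e-4, 1e-4):
            rec = run_cycles(
                s0, params, lv, n_cycles=1, period=t_end, dt=dt,
                rv_pressure_source=rv.rv_source(), record="last",
                stop_at_steady_state=False,
            )
            errs.append(np.max(np.abs(rec.V[-1] - ref.V[-1])))
        ratios = [errs[i] / errs[i + 1] for i in range(len(errs) - 1)]
        for r in ratios:
            assert 1.8 < r < 2.2

    def test_reference_is_deterministic(self, params):
        lv = ElastanceVentricle(E_ES=params.E_ESLV)
        s0 = params.initial_state()
        t_eval = np.linspace(0, 0.5, 11)
        a = reference_solution(s0, params, lv, 0.5, t_eval=t_eval)
        b = reference_solution(s0, params, lv, 0.5, t_eval=t_eval)
        assert np.array_equal(a.V, b.V)


class TestRunCycles:
    def test_quiescent_at_unstressed_is_steady_immediately(self, params):
        state = SystemState(t=0.0, V=tuple(params.unstressed_split))
        rec = run_cycles(state, params, zero_source, n_cycles=3, dt=1e-3)
        assert rec.converged
        assert rec.cycles_run == 2  # one comparison cycle needed
        assert np.all(rec.Q == 0.0)

    def test_elastance_ventricle_reaches_periodic_steady_state(self, params):
        """Volume distribution settles to a periodic orbit (0.1 µL/cycle)."""
        act = TwitchActivation()
        lv = ElastanceVentricle(E_ES=params.E_ESLV, activation=act)
        rv = ElastanceVentricle(E_ES=params.E_ESRV, activation=act)
        rec = run_cycles(
            params.initial_state(), params, lv, n_cycles=100, dt=2e-4,
            rv_pressure_source=rv.rv_source(), record="last",
        )
        assert rec.converged
        assert rec.cycles_run <= 100

        # continuing from the fixed point does not move the orbit
        rec2 = run_cycles(
            SystemState(t=0.0, V=tuple(rec.V[-1])), params, lv,
            n_cycles=10, dt=2e-4, rv_pressure_source=rv.rv_source(),
            record="last", stop_at_steady_state=False,
        )
        assert abs(rec2.V[:, 0].max() - rec.V[:, 0].max()) < 2e-10

    def test_volume_conservation_and_valve_onewayness(self, params):
        act = TwitchActivation()
        lv = ElastanceVentricle(E_ES=params.E_ESLV, activation=act)
        rv = ElastanceVentricle(E_ES=params.E_ESRV, activation=act)
        rec = run_cycles(
            params.initial_state(), params, lv, n_cycles=10, dt=5e-5,
            rv_pressure_source=rv.rv_source(), record="all",
            stop_at_steady_state=False,
        )
        drift = np.max(np.abs(rec.V.sum(axis=1) - params.V_t)) / params.V_t
        assert drift < 1e-9
        for seg in ("AV", "TC", "PV", "MT"):
            assert rec.Q[:, SEGMENTS.index(seg)].min() >= 0.0

    def test_nonconvergence_is_flagged_not_raised(self, params):
        act = TwitchActivation()
        lv = ElastanceVentricle(E_ES=params.E_ESLV, activation=act)
        rec = run_cycles(
            params.initial_state(), params, lv, n_cycles=3, dt=1e-3
        )
        assert not rec.converged
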