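"""Protocol drivers: closed-loop coupling, Windkessel comparator, isometric
twitches and afterload sweeps.

These tests run the integrator at a 5 kHz tick (rather than the production
20 kHz) to keep the suite fast; the physics being asserted is qualitative
and tick-rate independent (the acceptance suite exercises the full rate).
"""

import math

import numpy as np
import pytest

from cvloop.core_model import (
    CirculationParameters,
    InvalidParameterError,
    SystemState,
    run_cycles,
)
from cvloop.energetics import fit_relation
from cvloop.protocols import (
    MuscleCoupler,
    WindkesselParameters,
    end_diastolic_length,
    energetics_from_record,
    insilico_sweep,
    restretch_onset_metrics,
    run_closed_loop,
    run_isometric,
    run_windkessel,
    sweep_afterload,
)

DT = 2e-4  # 5 kHz test tick


class TestWindkesselParameters:
    def test_maps_from_circulation(self, params):
        wk = WindkesselParameters.from_circulation(params, EDL=0.975)
        assert wk.Z_c == params.R_AV
        assert wk.C == params.C_AO
        assert wk.R_p == params.R_SYS
        assert wk.EDL == 0.975

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            WindkesselParameters(EDL=1.2)
        with pytest.raises(InvalidParameterError):
            WindkesselParameters(R_p=0.0)


class TestRunWindkessel:
    def test_every_cycle_starts_at_set_edl(self, muscle, params):
        for edl in (1.0, 0.975):
            wk = WindkesselParameters.from_circulation(params, EDL=edl)
            rec = run_windkessel(muscle, wk, n_cycles=120, dt=DT)
            assert rec.converged
            for m in rec.cycle_metrics[2:]:
                assert m["EDL"] / muscle.geometry.L_o == pytest.approx(
                    edl, abs=2e-3
                )
            assert rec.L[0] / muscle.geometry.L_o == pytest.approx(edl, abs=2e-3)

    def test_low_arterial_pressure_gives_isometric_twitch(self, muscle, params):
        """If LV pressure never overcomes the (enormous) arterial pressure,
        the muscle stays at EDL: zero loop area."""
        wk = WindkesselParameters(
            Z_c=params.R_AV, C=params.C_AO, R_p=1e15, EDL=1.0
        )
        rec = run_windkessel(muscle, wk, n_cycles=30, dt=DT,
                             p_ao0=1e6)  # pressurized beyond peak P_LV
        assert np.ptp(rec.L) == pytest.approx(0.0, abs=1e-12)
        en = energetics_from_record(muscle, rec)
        assert en.work == pytest.approx(0.0, abs=1e-15)

    def test_lower_edl_nests_at_shorter_lengths(self, muscle, params):
        wk_hi = WindkesselParameters.from_circulation(params, EDL=1.0)
        wk_lo = WindkesselParameters.from_circulation(params, EDL=0.975)
        rec_hi = run_windkessel(muscle, wk_hi, n_cycles=150, dt=DT)
        rec_lo = run_windkessel(muscle, wk_lo, n_cycles=150, dt=DT)
        assert rec_lo.L.max() < rec_hi.L.max()
        assert rec_lo.L.min() < rec_hi.L.min()


class TestRunIsometric:
    def test_anchor_at_optimal_length(self, muscle):
        rec = run_isometric(muscle, muscle.geometry.L_o, dt=1e-4)
        m = rec.cycle_metrics[0]
        expected = muscle.sigma_max + muscle.passive_stress(muscle.geometry.L_o)
        assert m["peak_total_stress"] == pytest.approx(expected, rel=1e-4)
        assert np.ptp(rec.L) == 0.0

    def test_length_sweep_recovers_programmed_relation(self, muscle):
        """Peak stress sampled at 5 lengths below L_o, fitted by quadratic
        regression, reproduces the virtual muscle's stress-length rule."""
        Lo = muscle.geometry.L_o
        rels = np.array([0.9, 0.925, 0.95, 0.975, 1.0])
        peaks = []
        for rel in rels:
            rec = run_isometric(muscle, rel * Lo, dt=1e-4)
            peaks.append(rec.cycle_metrics[0]["peak_total_stress"])
        fit = fit_relation(rels, np.array(peaks), order=2)
        programmed = np.array(
            [muscle.active_stress(r * Lo) + muscle.passive_stress(r * Lo)
             for r in rels]
        )
        assert np.all(np.abs(fit.fitted - programmed) / programmed.max() < 0.05)
        assert np.all(np.diff(peaks) > 0)

    def test_rejects_overstretch(self, muscle):
        with pytest.raises(InvalidParameterError):
            run_isometric(muscle, 1.1 * muscle.geometry.L_o)


@pytest.fixture(scope="module")
def high_load_record(muscle, params):
    return run_closed_loop(
        muscle, params.with_(R_SYS=800e9), n_cycles=250, dt=DT
    )


class TestClosedLoop:
    def test_reaches_steady_state_near_optimal_length(
        self, high_load_record, muscle
    ):
        rec = high_load_record
        assert rec.converged
        edl = end_diastolic_length(rec) / muscle.geometry.L_o
        assert 0.95 <= edl <= 1.0

    def test_length_never_exceeds_optimal(self, high_load_record, muscle):
        assert high_load_record.L.max() <= muscle.geometry.L_o * (1 + 1e-12)

    def test_restretch_begins_before_full_relaxation(
        self, high_load_record, muscle
    ):
        m = restretch_onset_metrics(high_load_record, muscle)
        assert m["active_stress_at_onset"] > 0.0
        assert m["stress_decaying"]

    def test_velocity_is_length_derivative(self, high_load_record):
        rec = high_load_record
        np.testing.assert_allclose(
            rec.dLdt, np.gradient(rec.L, rec.t), rtol=1e-12
        )


SWEEP_GRID = (800e9, 300e9, 115e9)


@pytest.fixture(scope="module")
def closed_sweep(muscle, params):
    return sweep_afterload(
        muscle, params, SWEEP_GRID, protocol="closed-loop",
        n_cycles=250, dt=DT,
    )


class TestSweeps:
    GRID = SWEEP_GRID

    def test_closed_loop_edl_monotone_nonincreasing(self, closed_sweep):
        edl = closed_sweep.EDL
        assert np.all(np.diff(edl) <= 1e-9)

    def test_afterload_preload_coupled(self, closed_sweep):
        """Lowering systemic resistance lowers EDL and end-systolic stress
        together."""
        es_stress = [
            float(p.record.sigma[np.argmin(p.record.L)])
            for p in closed_sweep.points
        ]
        assert np.all(np.diff(closed_sweep.EDL) < 0)
        assert np.all(np.diff(es_stress) < 0)

    def test_fixed_edl_constant_across_same_grid(self, muscle, params):
        res = sweep_afterload(
            muscle, params, self.GRID, protocol="fixed-EDL", edl=1.0,
            n_cycles=150, dt=DT,
        )
        assert np.all(np.abs(res.EDL - 1.0) < 2e-3)
        assert res.all_converged

    def test_energetics_attached_per_point(self, closed_sweep):
        for p in closed_sweep.points:
            en = p.energetics
            assert en.enthalpy == pytest.approx(en.work + en.heat_active)
            assert 0.0 <= en.efficiency < 1.0

    def test_rejects_nonmonotone_grid(self, muscle, params):
        with pytest.raises(InvalidParameterError):
            sweep_afterload(muscle, params, [800e9, 100e9, 300e9])

    def test_rejects_unknown_protocol(self, muscle, params):
        with pytest.raises(InvalidParameterError):
            sweep_afterload(muscle, params, [800e9], protocol="bogus")


class TestWindkesselLimitEquivalence:
    def test_clamped_ring_matches_three_element_model(self, muscle, params):
        """With the venous/pulmonary compartments clamped and the mitral
        path disabled, one twitch of the closed-loop model reproduces the
        three-element Windkessel trajectory exactly (same tick, same
        discretization)."""
        u = params.unstressed_split
        pao0 = 3000.0
        V0 = (params.V_LV_init, u[1] + params.C_AO * pao0, u[2],
              0.23e-6, u[4], u[5])
        coup = MuscleCoupler(muscle)
        rec_cl = run_cycles(
            SystemState(t=0.0, V=V0), params, coup,
            n_cycles=1, period=0.5, dt=1e-4,
            pressure_clamp={"VC": 0.0}, blocked_segments=("MT",),
            record="all", stop_at_steady_state=False,
        )
        rec_cl = coup.annotate(rec_cl)
        wk = WindkesselParameters.from_circulation(params, EDL=1.0)
        rec_wk = run_windkessel(muscle, wk, n_cycles=1, dt=1e-4,
                                p_ao0=pao0, record="all")
        # compare up to the comparator's restretch onset
        L = rec_wk.L
        i_on = np.flatnonzero(L <= L.min() + 1e-9 * L.max())[-1]
        assert i_on > 1000  # a real ejection occurred
        np.testing.assert_allclose(
            rec_cl.V[:i_on, 0], rec_wk.V[:i_on, 0], rtol=1e-9
        )
        np.testing.assert_allclose(
            rec_cl.P[:i_on, 1], rec_wk.P[:i_on, 1], rtol=1e-9, atol=1e-9
        )


class TestInsilico:
    def test_preload_and_afterload_rise_with_systemic_resistance(self, params):
        pts = insilico_sweep(
            params, r_sys_values=(50e9, 175e9, 500e9), n_cycles=150, dt=DT
        )
        edv = [p["EDV"] for p in pts]
        plv = [p["P_LV_peak"] for p in pts]
        assert all(p["converged"] for p in pts)
        assert np.all(np.diff(edv) > 0)
        assert np.all(np.diff(plv) > 0)

    def test_espvr_passes_through_origin(self, params):
        """End-systolic (P/V) points at different loads share the slope
        E_ES through the origin: the linear end-systolic relation with
        zero unloaded volume."""
        pts = insilico_sweep(
            params, r_sys_values=(115e9, 300e9), n_cycles=150, dt=DT
        )
        for p in pts:
            rec = p["record"]
            ratio_peak = np.max(rec.P[:, 0] / np.maximum(rec.V[:, 0], 1e-12))
            # max over the cycle of P/(E_ES·V) equals the activation peak, 1
            assert ratio_peak == pytest.approx(params.E_ESLV, rel=5e-3)
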