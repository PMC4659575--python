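"""Coupled-cell integration: kernel accuracy, pacing, biomarkers."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from atriomech.ionic import build_cell_parameters, BASE_PARAMETERS
from atriomech.ionic.crn import gate_inf_tau, INITIAL_V
from atriomech.cell import (
    initial_state,
    check_state,
    cell_rhs_factory,
    build_lut,
    pack_params,
    pace_beats,
    integrate_record,
    apd90,
    compute_biomarkers,
    percent_change,
    PacingProtocol,
    CaptureFailure,
    run_pacing,
)
from atriomech.cell.state import I_V, I_GATES, I_NAI, I_CAREL
from atriomech.cell.biomarkers import NoActionPotential, Unrepolarized


class TestKernelAgainstReferenceSolver:
    def test_one_beat_matches_adaptive_stiff_solve(self, rice):
        """Rush-Larsen fixed-step vs BDF at tight tolerance over one beat."""
        p = BASE_PARAMETERS
        pv = pack_params(p, rice)
        dt = 0.01
        lut, aux = build_lut(dt)
        y = initial_state(rice)
        rec = integrate_record(y, pv, lut, aux, dt, 600.0,
                               np.array([10.0]), 2.0, 2000.0, 0.5)

        def stim(t):
            return 2000.0 if 10.0 <= t < 12.0 else 0.0

        rhs = cell_rhs_factory(p, rice, stim=stim)
        sol = solve_ivp(rhs, (0, 600.0), initial_state(rice), method="BDF",
                        rtol=1e-8, atol=1e-10, max_step=0.5, dense_output=True)
        Vref = sol.sol(rec[:, 0])[I_V]
        err = np.abs(rec[:, 1] - Vref)
        t = rec[:, 0]
        outside_upstroke = (t < 9.0) | (t > 18.0)
        assert err[outside_upstroke].max() < 1.0  # mV
        apd_kernel = apd90(t, rec[:, 1], v_dias=rec[0, 1])
        apd_ref = apd90(t, Vref, v_dias=Vref[0])
        assert abs(apd_kernel - apd_ref) < 2.0  # ms

    def test_resting_state_is_stable(self, rice):
        """Unstimulated base model stays at the published resting potential."""
        pv = pack_params(BASE_PARAMETERS, rice, coupled=False)
        dt = 0.01
        lut, aux = build_lut(dt)
        y = initial_state(rice)
        rec = integrate_record(y, pv, lut, aux, dt, 2000.0,
                               np.array([]), 2.0, 0.0, 10.0)
        assert np.all(np.abs(rec[:, 1] - INITIAL_V) < 1.0)


class TestRushLarsenProperties:
    def test_long_step_reaches_steady_state(self):
        """At frozen V, the exponential update lands on the gate target."""
        V = -20.0
        inf, tau = gate_inf_tau(V)
        g0 = np.full(12, 0.5)
        g = inf + (g0 - inf) * np.exp(-1e6 / tau)
        assert np.allclose(g, inf)

    def test_small_step_matches_forward_euler_to_first_order(self):
        V = -50.0
        inf, tau = gate_inf_tau(V)
        g0 = np.full(12, 0.3)
        for dt in (1e-3, 1e-4):
            rl = inf + (g0 - inf) * np.exp(-dt / tau)
            fe = g0 + dt * (inf - g0) / tau
            assert np.all(np.abs(rl - fe) < (dt / tau) ** 2 * np.abs(inf - g0) + 1e-15)

    def test_gates_bounded_whatever_the_step(self, rice):
        pv = pack_params(build_cell_parameters("RA/PM", "af"), rice)
        dt = 0.01
        lut, aux = build_lut(dt)
        y = initial_state(rice)
        pace_beats(y, pv, lut, aux, dt, 3, 300.0, 2.0, 8000.0)
        check_state(y)


class TestPacing:
    def test_zero_amplitude_stimulus_raises_capture_failure(self):
        with pytest.raises(CaptureFailure):
            run_pacing("RA/PM", "control",
                       PacingProtocol(s1_count=2, stim_amplitude=1e-6))

    def test_deterministic_given_protocol(self):
        proto = PacingProtocol(s1_count=5, stim_amplitude=4000.0)
        a = run_pacing("RA/PM", "control", proto)
        b = run_pacing("RA/PM", "control", proto)
        assert a.biomarkers == b.biomarkers
        assert np.array_equal(a.V, b.V)

    def test_apd_drift_small_at_steady_state(self, ra_control):
        last10 = ra_control.beats["apd90"].iloc[-10:]
        assert last10.max() - last10.min() < 1.0  # ms

    def test_biomarkers_insensitive_to_halving_dt(self):
        apds = []
        for dt in (0.01, 0.005):
            tr = run_pacing("RA/PM", "control",
                            PacingProtocol(s1_count=20, dt=dt,
                                           stim_amplitude=4000.0,
                                           record_dt=0.05))
            apds.append(tr.biomarkers.apd90)
        assert abs(apds[0] - apds[1]) < 0.5  # ms

    def test_af_remodeling_decreases_all_mechanical_biomarkers(self, ra_control, ra_af):
        c, a = ra_control.biomarkers, ra_af.biomarkers
        assert a.apd90 < c.apd90
        assert a.ca_sys < c.ca_sys
        assert a.sl_shortening < c.sl_shortening
        assert a.force_peak < c.force_peak

    def test_s2_premature_beat_is_shorter(self):
        proto = PacingProtocol(s1_count=10, s2_interval=400.0,
                               stim_amplitude=4000.0)
        tr = run_pacing("RA/PM", "control", proto)
        assert tr.s2_biomarkers is not None
        assert tr.s2_biomarkers.apd90 < tr.biomarkers.apd90

    def test_state_invariants_after_long_pacing(self, ra_control):
        check_state(ra_control.final_state)


class TestBiomarkers:
    def test_triangular_ap_has_analytic_apd90(self):
        t = np.linspace(0.0, 200.0, 2001)
        V = 20.0 - 0.5 * t  # 20 mV down to -80 mV over 200 ms
        assert np.isclose(apd90(t, V), 180.0, atol=0.2)

    def test_constant_trace_is_not_an_ap(self):
        t = np.linspace(0, 100, 500)
        with pytest.raises(NoActionPotential):
            apd90(t, np.full_like(t, -80.0))

    def test_unrepolarized_ap_is_flagged(self):
        t = np.linspace(0, 100, 500)
        V = np.where(t < 5, -80 + 20 * t, 20.0)  # upstroke then frozen plateau
        with pytest.raises(Unrepolarized):
            apd90(t, V, v_dias=-80.0)

    def test_systolic_below_diastolic_rejected(self):
        t = np.linspace(0, 300, 600)
        V = -80 + 100 * np.exp(-((t - 10) / 30) ** 2)
        with pytest.raises(ValueError):
            compute_biomarkers(t, V, Cai=np.full_like(t, np.nan))


class TestPercentChange:
    @pytest.mark.parametrize(
        "control, test, expected",
        [(1.0, 1.0, 0.0), (1.0, 0.18, 82.0), (274.0, 188.0, 31.4)],
    )
    def test_reduction_convention(self, control, test, expected):
        assert np.isclose(percent_change(control, test), expected, atol=0.1)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
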