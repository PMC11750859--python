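import math

import numpy as np
import pytest

from mossyfiber.exceptions import SimulationDiverged, SteadyStateNotConverged
from mossyfiber.fixtures import make_passive_references
from mossyfiber.morphology import build_mossy_fiber, site_index
from mossyfiber.protocols import Protocol
from mossyfiber.solver import (
    CableSolver,
    assemble_axial_coupling,
    balance_leak_reversal,
    init_state,
    run,
    steady_state,
    step,
)


class TestAxialCoupling:
    def test_matches_hand_computed_value_for_thin_axon(self):
        # two identical segments: d = 0.2 um, L = 1 um, R_i = 110 Ohm cm
        # rho = R_i * L / (pi d^2/4)
        #     = 110 * 1e-4 cm / (pi * (0.2e-4 cm)^2 / 4) = 3.5014e7 Ohm
        # coupling = 1/rho Siemens = 2.856e-5 mS
        cfg = {"geometry": {
            "soma": {"diameter_um": 0.2, "length_um": 1.0},
            "axon": {"count": 1, "length_um": 1.0, "diameter_um": 0.2},
            "bouton": {"count": 0}}}
        m = build_mossy_fiber(cfg)
        g = assemble_axial_coupling(m)
        rho = 110.0 * 1e-4 / (math.pi * (0.2e-4) ** 2 / 4.0)
        assert g.shape == (1,)
        assert g[0] == pytest.approx(1e3 / rho, rel=1e-12)

    def test_symmetric_tridiagonal_structure(self, default_model):
        g = assemble_axial_coupling(default_model)
        # one coupling per interface of the chain, all positive
        assert g.shape == (default_model.n_segments - 1,)
        assert np.all(g > 0)

    def test_doubling_ri_halves_every_coupling(self, default_model):
        g1 = assemble_axial_coupling(default_model)
        m2 = build_mossy_fiber({"passive": {"r_i_ohm_cm": 220.0}})
        g2 = assemble_axial_coupling(m2)
        np.testing.assert_allclose(g2, g1 / 2.0, rtol=1e-12)


class TestPassiveDynamics:
    def test_rc_step_response_matches_analytic(self, isopotential_model):
        """Passive isopotential patch: V follows V0 + IR(1 - e^(-t/tau)),
        tau = R_m C_m = 10 ms, within 1% of the step amplitude."""
        m = isopotential_model
        ref = make_passive_references()
        assert ref.tau_m_ms == pytest.approx(10.0)
        solver = CableSolver(m, ())
        state = solver.init_state()
        dt, i_na = 0.01, 0.01
        i_vec = np.zeros(m.n_segments)
        i_vec[0] = i_na * 1e-3  # nA -> uA
        n = int(50.0 / dt)
        v = np.empty(n + 1)
        v[0] = state.v_mv[0]
        for k in range(n):
            solver.step(state, dt, i_vec)
            v[k + 1] = state.v_mv[0]
        t = np.arange(n + 1) * dt
        v_ref = ref.rc_step_response(t, -80.0, i_na, m.total_area_cm2)
        amplitude = v_ref[-1] - v_ref[0]
        assert np.max(np.abs(v - v_ref)) < 0.01 * amplitude

    def test_first_order_convergence_in_dt(self, isopotential_model):
        """Backward Euler: the error of the passive transient halves when
        dt halves."""
        m = isopotential_model
        ref = make_passive_references()
        i_vec = np.zeros(m.n_segments)
        i_vec[0] = 0.01 * 1e-3

        def error_at(dt):
            solver = CableSolver(m, ())
            state = solver.init_state()
            n = int(round(5.0 / dt))
            for _ in range(n):
                solver.step(state, dt, i_vec)
            v_ref = ref.rc_step_response(5.0, -80.0, 0.01, m.total_area_cm2)
            return abs(state.v_mv[0] - v_ref)

        ratio = error_at(0.04) / error_at(0.02)
        assert 1.6 < ratio < 2.4

    def test_charge_relaxes_monotonically_to_leak_equilibrium(
            self, thin_cable_model):
        """Passive cable, no injection: total membrane charge deviation from
        the leak equilibrium decays monotonically."""
        m = thin_cable_model
        solver = CableSolver(m, ())
        state = solver.init_state()
        state.v_mv[:50] += 20.0  # local perturbation
        c = solver.c_abs_uf
        dev = [float(np.sum(c * (state.v_mv - m.e_leak)))]
        for _ in range(500):
            solver.step(state, 0.5)
            dev.append(float(np.sum(c * (state.v_mv - m.e_leak))))
        dev = np.abs(dev)
        assert np.all(np.diff(dev) <= 1e-15)
        assert dev[-1] < 1e-3 * dev[0]

    def test_equilibrium_persists_for_one_second(
            self, isopotential_model, generic_profile):
        """Balanced leak reversal + steady-state gates: V stays within
        0.5 mV of rest over 1 s of active integration."""
        from mossyfiber.channels import make_variant
        chans = make_variant("inactivating", profile=generic_profile)
        m = balance_leak_reversal(isopotential_model, chans, -80.0)
        solver = CableSolver(m, chans)
        state = solver.init_state(-80.0)
        for _ in range(10_000):
            solver.step(state, 0.1)
        assert np.max(np.abs(state.v_mv + 80.0)) < 0.5


class TestSteadyState:
    def test_uniform_passive_model_rests_at_leak_reversal(
            self, isopotential_model):
        v = steady_state(isopotential_model, ())
        np.testing.assert_allclose(v, -80.0, atol=1e-6)

    def test_sealed_end_cable_attenuation_matches_cosh_profile(
            self, thin_cable_model):
        """One end held 10 mV above rest: the steady-state profile matches
        cosh((L-x)/lambda)/cosh(L/lambda) within 0.5%."""
        m = thin_cable_model
        v = steady_state(m, (), clamp={0: -70.0}, tolerance_mv_per_ms=1e-6,
                         dt_ms=1.0)
        ref = make_passive_references(diameter_um=0.2)
        n = m.n_segments
        x = np.arange(n) * 1.0            # node centres, 1 um spacing
        L = (n - 0.5) * 1.0               # sealed outer edge of last segment
        att_sim = (v + 80.0) / 10.0
        att_ref = ref.cable_attenuation(x, L)
        assert np.max(np.abs(att_sim - att_ref) / att_ref) < 0.005

    def test_nonconvergence_reports_residual(self, thin_cable_model):
        with pytest.raises(SteadyStateNotConverged) as exc:
            steady_state(thin_cable_model, (), tolerance_mv_per_ms=1e-12,
                         dt_ms=0.5, t_cap_ms=5.0, min_t_ms=0.0)
        assert exc.value.residual > 1e-12


class TestActiveDynamics:
    def test_evoked_spike_peak_time_converges_with_dt(self, default_model):
        """A single somatic AP: peak time at dt = 0.1 ms within 0.2 ms of a
        10x finer reference."""
        from mossyfiber.analysis import detect_spikes
        base = Protocol(n_pulses=1, t_pre_ms=30.0, t_post_ms=20.0,
                        recording_sites=("soma",))
        peaks = {}
        for dt in (0.1, 0.01):
            ts = run(default_model, base.with_(dt_ms=dt))
            evs = detect_spikes(ts.time_ms, ts["soma"])
            assert len(evs) == 1
            peaks[dt] = evs[0].t_peak_ms
        assert abs(peaks[0.1] - peaks[0.01]) < 0.2

    def test_propagation_delay_reciprocity(self, generic_profile):
        """Uniform-diameter active cable: orthodromic and antidromic delays
        between two mirror-symmetric sites agree within 5%."""
        from mossyfiber.analysis import detect_spikes
        from mossyfiber.channels import make_variant
        cfg = {"geometry": {
            "soma": {"diameter_um": 1.0, "length_um": 200.0},
            "axon": {"count": 1, "length_um": 200.0, "diameter_um": 1.0},
            "bouton": {"count": 0}},
            "densities_ms_cm2": {"na": {"soma": 50.0, "axon": 50.0,
                                        "bouton": 50.0}}}
        m = build_mossy_fiber(cfg)
        chans = make_variant("inactivating", profile=generic_profile)

        def delay(inject, rec_from, rec_to):
            prot = Protocol(n_pulses=1, amplitude_na=0.5, t_pre_ms=30.0,
                            t_post_ms=20.0, injection_site=inject,
                            recording_sites=(rec_from, rec_to))
            ts = run(m, prot, channels=chans)
            t_from = detect_spikes(ts.time_ms, ts[rec_from])[0].t_peak_ms
            t_to = detect_spikes(ts.time_ms, ts[rec_to])[0].t_peak_ms
            return t_to - t_from

        d_ortho = delay("soma", "soma", "axon_1")
        d_anti = delay("axon_1", "axon_1", "soma")
        assert d_ortho > 0 and d_anti > 0
        assert abs(d_ortho - d_anti) <= 0.05 * max(d_ortho, d_anti)

    def test_divergence_raises_with_location(self, isopotential_model):
        solver = CableSolver(isopotential_model, ())
        state = solver.init_state()
        i_vec = np.zeros(isopotential_model.n_segments)
        i_vec[0] = 1e9
        with pytest.raises(SimulationDiverged) as exc:
            solver.step(state, 0.1, i_vec)
        assert exc.value.t_ms == pytest.approx(0.1)


class TestRun:
    def test_zero_pulses_gives_flat_traces_near_rest(self, default_model):
        prot = Protocol(n_pulses=0, t_pre_ms=100.0, t_post_ms=100.0)
        ts = run(default_model, prot)
        for site in ts.sites:
            v = ts[site]
            # settled near rest (small offset from resting gate activation)
            assert np.all(np.abs(v + 80.0) < 5.0)
            # late drift is slow (set by the slow inactivation gate settling)
            assert np.max(v[-100:]) - np.min(v[-100:]) < 0.2

    def test_run_is_bit_deterministic(self, default_model):
        prot = Protocol(n_pulses=2, t_pre_ms=20.0, t_post_ms=20.0)
        t1 = run(default_model, prot)
        t2 = run(default_model, prot)
        for site in t1.sites:
            np.testing.assert_array_equal(t1[site], t2[site])

    def test_functional_step_matches_solver_class(self, isopotential_model,
                                                  inactivating_channels):
        s1 = init_state(isopotential_model, inactivating_channels)
        s2 = s1.copy()
        solver = CableSolver(isopotential_model, inactivating_channels)
        step(isopotential_model, inactivating_channels, s1, 0.1)
        solver.step(s2, 0.1)
        np.testing.assert_array_equal(s1.v_mv, s2.v_mv)

    def test_g_na_override_rescales_axon_not_soma(self, default_model):
        prot = Protocol(n_pulses=0, t_pre_ms=1.0, t_post_ms=0.0,
                        g_na_ms_cm2=60.0)
        from mossyfiber.solver import _model_for_protocol
        m2 = _model_for_protocol(default_model, prot)
        na = m2.channel_densities["na"]
        assert np.all(na[default_model.landmark_slice("soma")] == 10.0)
        assert np.all(na[default_model.landmark_slice("axon_5")] == 60.0)
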