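"""RC membrane integrator, exact oracle, capacitance study and virtual rig."""

import numpy as np
import pytest

from tests.conftest import C_GRID

from gabaclamp.conductance import make_template
from gabaclamp.errors import ParameterError, ProtocolError
from gabaclamp.membrane_sim import (
    ProtocolSpec,
    RCParams,
    SpikingCellParams,
    capacitance_sweep,
    closed_form_rc,
    run_virtual_rig,
    simulate_rc,
)


class TestSimulateRC:
    def test_no_stimulus_at_equilibrium_is_constant(self, rc):
        tr = simulate_rc(rc, None, duration=100.0)
        np.testing.assert_allclose(tr.samples, rc.e_leak, atol=1e-12)

    def test_leak_relaxation_follows_exp_with_tau_m(self, rc):
        tr = simulate_rc(rc, None, duration=80.0, v0=rc.e_leak + 5.0)
        ref = rc.e_leak + 5.0 * np.exp(-tr.times / rc.tau_m)
        # forward Euler at dt=0.1 on an 8.8 ms time constant: O(dt) accuracy
        assert np.max(np.abs(tr.samples - ref)) < 0.05

    def test_stability_bound_enforced(self):
        with pytest.raises(ParameterError):
            RCParams(r_mohm=100.0, c_pf=5.0, dt_sim=0.1)  # tau_m = 0.5 ms

    def test_duration_must_cover_the_transient(self, rc, library):
        with pytest.raises(ParameterError):
            simulate_rc(rc, library["g5_tau10"], duration=40.0, trigger=10.0)

    def test_response_is_a_single_depolarizing_transient(self, rc, library):
        tr = simulate_rc(rc, library["g5_tau7"], duration=300.0, trigger=20.0)
        peak = tr.samples.max()
        assert peak > rc.e_leak + 5.0
        assert tr.samples[-1] == pytest.approx(rc.e_leak, abs=0.01)


class TestClosedForm:
    def test_initial_condition(self, rc, library):
        assert closed_form_rc(rc, library["g1_tau7"], 0.0, v0=-60.0) == pytest.approx(-60.0)

    def test_pure_leak_is_analytic(self, rc):
        t = np.linspace(0.0, 50.0, 7)
        v = closed_form_rc(rc, None, t, v0=rc.e_leak + 4.0)
        ref = rc.e_leak + 4.0 * np.exp(-t / rc.tau_m)
        np.testing.assert_allclose(v, ref, atol=1e-10)

    def test_agrees_with_high_resolution_euler(self, library):
        """Grid-refinement oracle: a dt=1e-3 ms Euler run converges onto the
        integrating-factor solution (error < 5e-3 mV, consistent with the
        first-order error constant of the largest-conductance condition)."""
        p = RCParams(737.0, 12.0, dt_sim=1e-3)
        tpl = library["g10_tau7"]
        tr = simulate_rc(p, tpl, duration=60.0, trigger=10.0)
        sel = slice(0, tr.n, 200)
        cf = closed_form_rc(p, tpl, tr.times[sel], trigger=10.0)
        assert np.max(np.abs(tr.samples[sel] - cf)) < 5e-3

    def test_euler_error_is_first_order_in_dt(self, library):
        """The Euler deviation from the exact solution scales linearly with
        dt — the signature of a correct forward-Euler integrator against a
        correct oracle."""
        tpl = library["g10_tau7"]
        errs = {}
        for dt in (0.1, 0.01):
            p = RCParams(737.0, 8.0, dt_sim=dt)
            tr = simulate_rc(p, tpl, duration=80.0, trigger=10.0)
            step = max(1, int(round(0.1 / dt)))
            cf = closed_form_rc(p, tpl, tr.times[::step], trigger=10.0)
            errs[dt] = float(np.max(np.abs(tr.samples[::step] - cf)))
        assert errs[0.01] < 0.1
        assert 5.0 < errs[0.1] / errs[0.01] < 20.0  # ~linear convergence


class TestCapacitanceSweep:
    def test_amplitude_decreases_and_latency_increases_with_c(self, rc, library):
        res = capacitance_sweep(rc, library["g5_tau7"], c_values=C_GRID)
        amp = res.table["amplitude_mV"].to_numpy()
        lat = res.table["latency_ms"].to_numpy()
        assert np.all(np.diff(amp) < 0)
        assert np.all(np.diff(lat) > 0)
        # behaviour matches the exact solution's features, not just Euler's
        tpl = library["g5_tau7"]
        t = np.arange(0.0, 500.0, 0.1)
        exact_amp = []
        for c in C_GRID:
            v = closed_form_rc(RCParams(737.0, c), tpl, t, trigger=50.0)
            exact_amp.append(v.max() + 65.0)
        assert np.all(np.diff(exact_amp) < 0)

    def test_decay_time_increases_with_c_and_template_tau(self, rc, library):
        res7 = capacitance_sweep(rc, library["g5_tau7"], c_values=C_GRID)
        res10 = capacitance_sweep(rc, library["g5_tau10"], c_values=C_GRID)
        assert np.all(np.diff(res7.table["decay_80_20_ms"]) > 0)
        assert np.all(
            res10.table["decay_80_20_ms"].to_numpy()
            > res7.table["decay_80_20_ms"].to_numpy()
        )

    def test_degenerate_single_c_equals_direct_simulation(self, rc, library):
        res = capacitance_sweep(rc, library["g2_tau7"], c_values=[rc.c_pf])
        direct = simulate_rc(rc, library["g2_tau7"], duration=500.0, trigger=50.0)
        np.testing.assert_array_equal(res.raw[rc.c_pf].samples, direct.samples)

    def test_normalized_traces_have_unit_peak(self, rc, library):
        res = capacitance_sweep(rc, library["g10_tau10"], c_values=(8.0, 16.0))
        for ts in res.normalized.values():
            assert ts.samples.max() == pytest.approx(1.0, abs=0.01)


class TestVirtualRig:
    def _proto(self, **kw):
        kw.setdefault("templates", ["g1_tau7", "g5_tau7", "g10_tau10"])
        kw.setdefault("pre_trigger", 100.0)
        kw.setdefault("post_trigger", 600.0)
        return ProtocolSpec(**kw)

    def test_baselines_inside_required_window(self, rc):
        rig = run_virtual_rig(rc, self._proto(), seed=0, noise_sd=0.15)
        for ss in rig.sweeps.values():
            for sw in ss.sweeps:
                seg = sw.samples[: sw.index_at(ss.trigger_time)]
                assert np.all(seg > -66.5) and np.all(seg < -63.5)

    def test_ten_repetitions_per_template(self, rc):
        rig = run_virtual_rig(rc, self._proto(repetitions=10), seed=1)
        assert all(ss.n_sweeps == 10 for ss in rig.sweeps.values())
        assert len(rig.sweeps) == 3

    def test_fixed_seed_is_bit_identical(self, rc):
        a = run_virtual_rig(rc, self._proto(), seed=7, noise_sd=0.2)
        b = run_virtual_rig(rc, self._proto(), seed=7, noise_sd=0.2)
        for tid in a.sweeps:
            for s1, s2 in zip(a.sweeps[tid].sweeps, b.sweeps[tid].sweeps):
                np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_order_independence_for_linear_cell(self, rc):
        asc = run_virtual_rig(rc, self._proto(order="ascending"), seed=2)
        desc = run_virtual_rig(rc, self._proto(order="descending"), seed=2)
        for tid in asc.sweeps:
            avg_a = asc.sweeps[tid].as_array().mean(axis=0)
            avg_d = desc.sweeps[tid].as_array().mean(axis=0)
            np.testing.assert_array_equal(avg_a, avg_d)

    def test_unreachable_baseline_target_is_a_protocol_error(self, rc):
        with pytest.raises(ProtocolError):
            run_virtual_rig(rc, self._proto(), seed=0, v_target=-60.0)

    def test_spiking_log_matches_splices(self, rc):
        cell = SpikingCellParams(
            rc=rc, ap_threshold_true=-48.0, firing_propensity={"g10_tau10": 0.7}
        )
        rig = run_virtual_rig(cell, self._proto(), seed=3)
        ss, log = rig.sweeps["g10_tau10"], rig.log["g10_tau10"]
        fired = [e["fired"] for e in log]
        assert any(fired) and not all(fired)
        for sw, entry in zip(ss.sweeps, log):
            has_spike = sw.samples.max() > -40.0  # spike peak ~ threshold + 80
            assert has_spike == entry["fired"]
        # no spikes in templates with zero propensity
        assert np.all(rig.sweeps["g1_tau7"].as_array() < -40.0)

    def test_loop_delay_emulation_barely_perturbs_the_response(self, rc):
        ideal = run_virtual_rig(rc, self._proto(), seed=0)
        delayed = run_virtual_rig(rc, self._proto(loop_delay_us=21.29), seed=0)
        a = ideal.sweeps["g10_tau10"].sweeps[0].samples
        b = delayed.sweeps["g10_tau10"].sweeps[0].samples
        assert 0.0 < np.max(np.abs(a - b)) < 1.0


def test_spike_geometry_infeasible_combination_is_rejected():
    from gabaclamp.membrane_sim import make_spike_fixture

    with pytest.raises(ParameterError):
        make_spike_fixture(v_threshold=-45.0, fwhm=1.4, ahp_time=2.0)
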