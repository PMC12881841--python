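"""Baseline gating, sweep classification and dcPSP feature extraction."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gabaclamp.dcpsp_analysis import (
    analyze_sweepset,
    average_dcpsp,
    baseline_ok,
    classify_sweep,
    dcpsp_features,
)
from gabaclamp.errors import DataError, InsufficientEventsError, WindowError
from gabaclamp.membrane_sim import (
    ProtocolSpec,
    RCParams,
    SpikingCellParams,
    closed_form_rc,
    run_virtual_rig,
    simulate_rc,
)
from gabaclamp.trace_model import SweepSet, TimeSeries


def _flat(v, n=2000, dt=0.1):
    return TimeSeries(np.full(n, float(v)), dt, 0.0, "mV")


class TestBaselineOK:
    def test_constant_in_range_passes(self):
        assert baseline_ok(_flat(-65.0), trigger=50.0)

    def test_constant_out_of_range_fails(self):
        assert not baseline_ok(_flat(-63.0), trigger=50.0)

    def test_transient_violating_stability_fails(self):
        ts = _flat(-65.0)
        ts.samples[460:470] += 2.0  # 2 mV transient inside the last 10 ms
        assert not baseline_ok(ts, trigger=50.0, stability_tol=1.0)
        # the same transient within tolerance passes
        ts2 = _flat(-65.0)
        ts2.samples[460:470] += 0.8
        assert baseline_ok(ts2, trigger=50.0, stability_tol=1.0)

    def test_window_must_fit_before_trigger(self):
        with pytest.raises(WindowError):
            baseline_ok(_flat(-65.0), trigger=5.0, window=10.0)


class TestClassifySweep:
    def test_subthreshold_rc_sweep_is_psp_only(self, rc, library):
        tr = simulate_rc(rc, library["g10_tau7"], duration=400.0, trigger=50.0)
        assert classify_sweep(tr, trigger=50.0, avg_peak_latency=5.0).label == "psp_only"

    @pytest.mark.parametrize("delayed", [False, True])
    def test_spike_timing_splits_rising_vs_delayed(self, rc, delayed):
        cell = SpikingCellParams(
            rc=rc,
            ap_threshold_true=-47.0,
            firing_propensity=1.0,
            delayed_propensity=1.0 if delayed else 0.0,
        )
        proto = ProtocolSpec(templates=["g10_tau7"], pre_trigger=100.0, post_trigger=600.0)
        rig = run_virtual_rig(cell, proto, seed=2)
        sw = rig.sweeps["g10_tau7"].sweeps[0]
        entry = rig.log["g10_tau7"][0]
        assert entry["fired"] and entry["delayed"] == delayed
        # reference latency: peak of the spike-free response of the same cell
        passive = run_virtual_rig(rc, proto, seed=2).sweeps["g10_tau7"].sweeps[0]
        k = passive.index_at(100.0)
        ref = (k + int(np.argmax(passive.samples[k:]))) * passive.dt - 100.0
        got = classify_sweep(sw, trigger=100.0, avg_peak_latency=ref)
        assert got.label == ("ap_delayed" if delayed else "ap_rising")

    def test_ap_without_reference_is_deferred(self, rc):
        cell = SpikingCellParams(rc=rc, ap_threshold_true=-47.0, firing_propensity=1.0)
        proto = ProtocolSpec(templates=["g10_tau7"], pre_trigger=100.0, post_trigger=600.0)
        sw = run_virtual_rig(cell, proto, seed=4).sweeps["g10_tau7"].sweeps[0]
        got = classify_sweep(sw, trigger=100.0, avg_peak_latency=None)
        assert got.label == "ap_deferred" and got.deferred


class TestAverageDcPSP:
    def _sweepset(self, traces, trigger=50.0):
        return SweepSet(sweeps=traces, trigger_time=trigger)

    def test_mean_of_identical_sweeps_is_any_single_sweep(self, rc, library):
        tr = simulate_rc(rc, library["g5_tau7"], duration=400.0, trigger=50.0)
        ss = self._sweepset([tr.copy() for _ in range(10)])
        avg = average_dcpsp(ss)
        np.testing.assert_allclose(avg.samples, tr.samples, rtol=0, atol=1e-12)

    def test_failing_sweeps_are_excluded_from_the_average(self, rc, library):
        tr = simulate_rc(rc, library["g5_tau7"], duration=400.0, trigger=50.0)
        good = [tr.copy() for _ in range(6)]
        bad = [TimeSeries(tr.samples + 3.0, tr.dt, tr.t0, "mV") for _ in range(4)]
        labels = ["psp_only"] * 6 + ["baseline_fail"] * 4
        avg = average_dcpsp(self._sweepset(good + bad), labels=labels)
        np.testing.assert_allclose(avg.samples, tr.samples, rtol=0, atol=1e-12)

    def test_fewer_than_five_qualifying_sweeps_is_an_exclusion(self, rc, library):
        tr = simulate_rc(rc, library["g5_tau7"], duration=400.0, trigger=50.0)
        labels = ["psp_only"] * 4 + ["baseline_fail"] * 2
        with pytest.raises(InsufficientEventsError):
            average_dcpsp(self._sweepset([tr.copy() for _ in range(6)]), labels=labels)


class TestDcPSPFeatures:
    def test_features_match_dense_closed_form_oracle(self, library):
        """Latency, amplitude and 80/20 decay computed independently from the
        exact solution by dense evaluation and root bracketing."""
        p = RCParams(737.0, 12.0)
        tpl = library["g5_tau7"]
        trigger = 50.0
        t_dense = np.arange(0.0, 400.0, 0.01)
        v_dense = closed_form_rc(p, tpl, t_dense, trigger=trigger)
        baseline = p.e_leak
        k = int(np.argmax(v_dense))
        amp_o = v_dense[k] - baseline
        lat_o = t_dense[k] - trigger

        def v_of(t):
            return float(closed_form_rc(p, tpl, float(t), trigger=trigger))

        t80 = brentq(lambda t: v_of(t) - (baseline + 0.8 * amp_o), t_dense[k], 400.0)
        t20 = brentq(lambda t: v_of(t) - (baseline + 0.2 * amp_o), t80, 400.0)
        decay_o = t20 - t80

        avg = TimeSeries(
            closed_form_rc(p, tpl, np.arange(0.0, 400.0, 0.1), trigger=trigger),
            0.1, 0.0, "mV",
        )
        f = dcpsp_features(avg, trigger=trigger)
        assert f.amplitude == pytest.approx(amp_o, rel=1e-3)
        assert f.latency == pytest.approx(lat_o, abs=0.05)
        assert f.decay_80_20 == pytest.approx(decay_o, rel=1e-3)

    def test_zero_conductance_average_has_no_transient(self, rc):
        flat = simulate_rc(rc, None, duration=400.0)
        with pytest.raises(DataError):
            dcpsp_features(flat, trigger=50.0)

    def test_constant_offset_leaves_features_unchanged(self, rc, library):
        tr = simulate_rc(rc, library["g2_tau10"], duration=400.0, trigger=50.0)
        f1 = dcpsp_features(tr, trigger=50.0)
        f2 = dcpsp_features(
            TimeSeries(tr.samples + 3.3, tr.dt, tr.t0, "mV"), trigger=50.0
        )
        assert f2.latency == pytest.approx(f1.latency, abs=1e-9)
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-9)
        assert f2.decay_80_20 == pytest.approx(f1.decay_80_20, abs=1e-9)
        assert f2.baseline - f1.baseline == pytest.approx(3.3, abs=1e-9)


class TestAnalyzeSweepset:
    def test_partition_property_with_injected_failures(self, rc, library):
        proto = ProtocolSpec(templates=["g5_tau7"], pre_trigger=100.0, post_trigger=600.0)
        rig = run_virtual_rig(rc, proto, seed=6, noise_sd=0.15)
        ss = rig.sweeps["g5_tau7"]
        for k in (1, 4):  # push two baselines out of range
            ss.sweeps[k].samples += 2.0
        res = analyze_sweepset(ss)
        assert sum(res.counts.values()) == ss.n_sweeps
        assert res.counts["baseline_fail"] == 2
        assert res.counts["psp_only"] == 8
        assert res.features is not None
        assert res.features.n_traces_averaged == 8
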