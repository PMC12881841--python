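"""Seeded generator of a full virtual study.

Builds cohorts of model cells for the two-by-two design (3-week vs adult ×
VEH vs PNA) with the published group statistics as generating parameters:
per-group input resistance, series resistance and capacitance (means ± SEM,
converted to SDs via SD = SEM·√n with the per-group n), the age-dependent PSC
decay time constants (7.4 ± 0.13 ms SEM, n = 11 prepubertal; 9.9 ± 0.25 ms
SEM, n = 12 adult), PSC amplitudes with no group effect, and qualitative
firing-propensity structure: no cell fires at 1 or 2 nS, firing at 5 nS is
concentrated in 3-week controls, and delayed spikes occur only in 3-week PNA
cells.  Passive parameters are drawn from truncated normals bounded by the QC
ranges so generated cells pass QC unless violations are injected explicitly.

Every draw is seeded and the manifest records the ground truth per cell, so
the full pipeline (QC → detection → isolation/classification → averaging →
features → report) can be validated end to end against known parameters.

Firing propensities are illustrative, not estimates: the published data give
per-group responder counts and the 2–10-of-10 range of firing sweeps in
responders, from which per-sweep probabilities are not identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .errors import SpecError
from .membrane_sim import (
    ProtocolSpec,
    RCParams,
    RigResult,
    SpikingCellParams,
    run_virtual_rig,
    simulate_rc,
)
from .passive_qc import QCGate, circuit_response
from .trace_model import GROUPS, GroupLabel, SweepSet, TimeSeries

__all__ = [
    "GroupParams",
    "DEFAULT_GROUP_PARAMS",
    "DEFAULT_RESPONDER_FRACTIONS",
    "CohortSpec",
    "CellRecord",
    "generate_cohort",
    "generate_psc_recordings",
    "generate_dcpsp_recordings",
    "iter_dcpsp_recordings",
    "generate_membrane_tests",
]


@dataclass
class GroupParams:
    """Per-group generating statistics (mean, SEM, reference n)."""

    n_ref: int
    r_input: tuple[float, float]  # MΩ
    r_series: tuple[float, float]  # MΩ
    capacitance: tuple[float, float]  # pF
    psc_tau: tuple[float, float, int]  # (mean ms, SEM, n) — age-dependent
    psc_amplitude: tuple[float, float] = (30.0, 8.0)  # (mean pA, SD); no group effect

    def sd(self, which: str) -> float:
        mean_sem = getattr(self, which)
        return mean_sem[1] * np.sqrt(self.n_ref)

    @property
    def psc_tau_sd(self) -> float:
        mean, sem, n = self.psc_tau
        return sem * np.sqrt(n)


_TAU_PREPUBERTAL = (7.4, 0.13, 11)
_TAU_ADULT = (9.9, 0.25, 12)

DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "three_week_VEH": GroupParams(12, (767.905, 45.54), (15.33, 0.66), (10.37, 0.45), _TAU_PREPUBERTAL),
    "three_week_PNA": GroupParams(13, (690.51, 27.02), (14.32, 0.81), (12.02, 0.65), _TAU_PREPUBERTAL),
    "adult_VEH": GroupParams(14, (726.09, 55.24), (12.96, 0.91), (12.88, 0.47), _TAU_ADULT),
    "adult_PNA": GroupParams(12, (757.91, 59.37), (14.48, 1.02), (13.23, 0.76), _TAU_ADULT),
}

#: Fraction of cells per group that respond with spikes, per template.
#: 1 and 2 nS conductances never trigger spikes in any group; 5 nS firing is
#: concentrated in 3-week controls; 10 nS recruits some cells in every group,
#: most in 3-week controls and fewest in adult controls.
DEFAULT_RESPONDER_FRACTIONS: dict[str, dict[str, float]] = {
    "three_week_VEH": {"g5_tau7": 5 / 15, "g5_tau10": 6 / 15, "g10_tau7": 5 / 15, "g10_tau10": 7 / 14},
    "three_week_PNA": {"g10_tau7": 4 / 15, "g10_tau10": 4 / 13},
    "adult_VEH": {"g5_tau10": 1 / 13, "g10_tau7": 2 / 13, "g10_tau10": 1 / 13},
    "adult_PNA": {"g5_tau10": 2 / 10, "g10_tau7": 4 / 12, "g10_tau10": 6 / 14},
}

#: Probability that a firing sweep is a delayed spike, per group × template.
#: Delayed spikes are exclusive to the 3-week PNA group at 10 nS.
DEFAULT_DELAYED_FRACTIONS: dict[str, dict[str, float]] = {
    "three_week_PNA": {"g10_tau7": 0.5, "g10_tau10": 0.5},
}


@dataclass
class CohortSpec:
    """Specification of a virtual cohort."""

    n_cells: int | dict = 12  # per group, or a {group_label: n} mapping
    seed: int = 0
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    responder_fractions: dict = field(default_factory=lambda: dict(DEFAULT_RESPONDER_FRACTIONS))
    delayed_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DELAYED_FRACTIONS))
    noise_sd_mv: float = 0.15  # voltage noise on dcPSP sweeps
    psc_noise_sd_pa: float = 2.0  # current noise on PSC sweeps
    baseline_violation_rate: float = 0.1  # fraction of dcPSP sweeps offset out of range
    qc_gate: QCGate = field(default_factory=QCGate)

    def n_for(self, group: GroupLabel) -> int:
        if isinstance(self.n_cells, dict):
            return int(self.n_cells[str(group)])
        return int(self.n_cells)


@dataclass
class CellRecord:
    """One generated cell and its ground truth."""

    cell_id: str
    group: GroupLabel
    rc: RCParams
    r_series: float  # MΩ (recording property; not part of the RC model)
    psc_tau: float  # ms
    psc_amplitude: float  # pA (positive magnitude; events are inward)
    ap_amplitude: float
    ap_fwhm: float
    ahp_amplitude: float
    ahp_time: float


def _tn(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """One truncated-normal draw on [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(spec: CohortSpec) -> tuple[list[CellRecord], dict]:
    """Draw cell parameters for every group; returns cells and a manifest
    keyed by cell id with the full ground truth.

    Raises :class:`SpecError` if any generating mean sits more than 3 SD
    outside its QC range (the truncated draw would no longer resemble the
    requested distribution).
    """
    gate = spec.qc_gate
    for glabel, gp in spec.group_params.items():
        for which, (lo, hi) in (
            ("r_input", gate.r_input_range),
            ("r_series", gate.r_series_range),
            ("capacitance", gate.capacitance_range),
        ):
            mean = getattr(gp, which)[0]
            sd = gp.sd(which)
            if mean < lo - 3 * sd or mean > hi + 3 * sd:
                raise SpecError(f"{glabel}.{which} mean {mean} infeasible for QC range ({lo}, {hi})")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    cells: list[CellRecord] = []
    manifest: dict = {"seed": spec.seed, "cells": {}}
    for group in GROUPS:
        gp = spec.group_params[str(group)]
        for j in range(spec.n_for(group)):
            cid = f"{group}_{j:03d}"
            r_in = _tn(rng, gp.r_input[0], gp.sd("r_input"), *gate.r_input_range)
            r_s = _tn(rng, gp.r_series[0], gp.sd("r_series"), *gate.r_series_range)
            cap = _tn(rng, gp.capacitance[0], gp.sd("capacitance"), *gate.capacitance_range)
            tau = _tn(rng, gp.psc_tau[0], gp.psc_tau_sd, 2.0, 25.0)
            amp = _tn(rng, gp.psc_amplitude[0], gp.psc_amplitude[1], 10.0, 80.0)
            cell = CellRecord(
                cell_id=cid,
                group=group,
                rc=RCParams(r_mohm=r_in, c_pf=cap),
                r_series=r_s,
                psc_tau=tau,
                psc_amplitude=amp,
                ap_amplitude=_tn(rng, 80.0, 4.0, 60.0, 90.0),
                ap_fwhm=_tn(rng, 0.7, 0.06, 0.6, 0.9),
                ahp_amplitude=_tn(rng, -24.0, 1.5, -28.0, -18.0),
                ahp_time=_tn(rng, 2.85, 0.3, 2.4, 4.5),
            )
            cells.append(cell)
            manifest["cells"][cid] = {
                "group": str(group),
                "r_input_mohm": r_in,
                "r_series_mohm": r_s,
                "capacitance_pf": cap,
                "psc_tau_ms": tau,
                "psc_amplitude_pa": amp,
                "ap_amplitude_mv": cell.ap_amplitude,
                "ap_fwhm_ms": cell.ap_fwhm,
                "ahp_amplitude_mv": cell.ahp_amplitude,
                "ahp_time_ms": cell.ahp_time,
            }
    return cells, manifest


# ---------------------------------------------------------------------------
# PSC recordings (voltage clamp)
# ---------------------------------------------------------------------------

def _psc_shape(t_rel: np.ndarray, tau: float, tau_rise: float = 0.2) -> tuple[np.ndarray, float]:
    """Unit-peak PSC kernel (fast exponential rise, monoexponential decay)
    and the latency from onset to peak."""
    t_peak = tau_rise * np.log(1.0 + tau / tau_rise)
    raw = (1.0 - np.exp(-np.maximum(t_rel, 0.0) / tau_rise)) * np.exp(-np.maximum(t_rel, 0.0) / tau)
    raw[t_rel < 0] = 0.0
    peak = (1.0 - np.exp(-t_peak / tau_rise)) * np.exp(-t_peak / tau)
    return raw / peak, float(t_peak)


def generate_psc_recordings(
    cells: list[CellRecord],
    events_per_cell: int = 20,
    noise_sd: float = 2.0,
    seed: int = 0,
    mean_interval: float | None = None,
    dt: float = 0.05,
) -> dict[str, tuple[SweepSet, dict]]:
    """Voltage-clamp current sweeps with PSC trains of known timing and decay.

    With the default spacing (uniform 90–150 ms inter-event intervals) every
    event is isolated under the 50 ms rule; passing ``mean_interval`` (ms)
    switches to exponential spacing with that mean, deliberately violating
    isolation for some events to exercise the rule.  Events are inward
    (negative); per-event amplitudes jitter 10% around the cell mean.
    Returns, per cell id, the sweep set and the ground truth (event peak
    times, amplitudes, generating tau).
    """
    out: dict[str, tuple[SweepSet, dict]] = {}
    children = np.random.SeedSequence(seed).spawn(len(cells))
    for cell, child in zip(cells, children):
        rng = np.random.default_rng(child)
        if mean_interval is None:
            gaps = rng.uniform(90.0, 150.0, events_per_cell)
        else:
            gaps = 2.0 + rng.exponential(mean_interval, events_per_cell)
        onsets = 50.0 + np.cumsum(gaps)
        duration = onsets[-1] + 150.0
        n = int(round(duration / dt)) + 1
        t = np.arange(n) * dt
        i = np.zeros(n)
        truth_events = []
        for onset in onsets:
            amp = cell.psc_amplitude * (1.0 + 0.1 * rng.standard_normal())
            amp = max(amp, 5.0)
            shape, t_peak = _psc_shape(t - onset, cell.psc_tau)
            i -= amp * shape
            truth_events.append({"peak_time": onset + t_peak, "amplitude": -amp})
        if noise_sd > 0:
            i = i + rng.normal(0.0, noise_sd, n)
        ss = SweepSet(
            sweeps=[TimeSeries(i, dt, 0.0, "pA")],
            trigger_time=0.0,
            cell_id=cell.cell_id,
            group=cell.group,
            ljp_corrected=True,
        )
        out[cell.cell_id] = (ss, {"tau": cell.psc_tau, "events": truth_events})
    return out


# ---------------------------------------------------------------------------
# Dynamic-clamp recordings (current clamp)
# ---------------------------------------------------------------------------

def _spiking_params_for(
    cell: CellRecord,
    spec: CohortSpec,
    proto: ProtocolSpec,
    templates: dict,
    rng: np.random.Generator,
    v_target: float,
) -> tuple[SpikingCellParams, dict]:
    """Decide responder status per condition and pick a reachable threshold.

    The RC membrane carries no regenerative sodium conductance, so responder
    thresholds are placed just below the cell's own subthreshold peak for its
    smallest spiking condition (margin U(0.5, 2) mV); non-responder
    conditions are silenced through zero propensity regardless of threshold.
    """
    resp_frac = spec.responder_fractions.get(str(cell.group), {})
    del_frac = spec.delayed_fractions.get(str(cell.group), {})
    firing: dict[str, float] = {}
    delayed: dict[str, float] = {}
    responder_tids = []
    for tid in proto.templates:
        f = resp_frac.get(tid, 0.0)
        if f > 0 and rng.random() < f:
            responder_tids.append(tid)
            firing[tid] = float(rng.uniform(0.2, 1.0))  # 2–10 of 10 sweeps
            delayed[tid] = float(del_frac.get(tid, 0.0))
    threshold = -44.0  # nominal; irrelevant when nothing fires
    if responder_tids:
        i_hold = cell.rc.g_leak * (v_target - cell.rc.e_leak)
        peaks = []
        for tid in responder_tids:
            tpl = templates[tid]
            base = simulate_rc(
                cell.rc,
                tpl,
                duration=proto.pre_trigger + 10.0 * tpl.tau + 200.0,
                v0=v_target,
                trigger=proto.pre_trigger,
                i_inj=i_hold,
            )
            peaks.append(float(np.max(base.samples)))
        threshold = min(peaks) - float(rng.uniform(0.5, 2.0))
    sp = SpikingCellParams(
        rc=cell.rc,
        ap_threshold_true=threshold,
        ap_amplitude_true=cell.ap_amplitude,
        ap_fwhm_true=cell.ap_fwhm,
        ahp_amplitude_true=cell.ahp_amplitude,
        ahp_time_true=cell.ahp_time,
        firing_propensity=firing,
        delayed_propensity=delayed,
    )
    info = {"responder_templates": responder_tids, "ap_threshold": threshold}
    return sp, info


def iter_dcpsp_recordings(
    cells: list[CellRecord],
    proto: ProtocolSpec | None = None,
    spec: CohortSpec | None = None,
    seed: int = 0,
    templates: dict | None = None,
):
    """Yield ``(cell, sweepsets, cell_log)`` per cell — streaming form of
    :func:`generate_dcpsp_recordings` (a full cohort at protocol length is
    ~1 GB if materialized at once).

    ``cell_log`` records, per template, the rig's per-sweep spike log and the
    indices of sweeps whose baseline was deliberately offset out of range.
    """
    from .conductance import default_template_library

    proto = proto or ProtocolSpec()
    spec = spec or CohortSpec()
    templates = templates or default_template_library()
    low, high = proto.baseline_window
    v_target = 0.5 * (low + high)
    children = np.random.SeedSequence(seed).spawn(len(cells))
    for cell, child in zip(cells, children):
        rng = np.random.default_rng(child)
        rig_seed = int(rng.integers(0, 2**31 - 1))
        sp, info = _spiking_params_for(cell, spec, proto, templates, rng, v_target)
        rig: RigResult = run_virtual_rig(
            sp,
            proto,
            seed=rig_seed,
            templates=templates,
            noise_sd=spec.noise_sd_mv,
            cell_id=cell.cell_id,
            group=cell.group,
        )
        violations: dict[str, list[int]] = {}
        for tid, ss in rig.sweeps.items():
            bad = [
                k
                for k in range(ss.n_sweeps)
                if rng.random() < spec.baseline_violation_rate
            ]
            for k in bad:
                ss.sweeps[k].samples += 2.0  # shifts the baseline above −63.5 mV
            violations[tid] = bad
        cell_log = {"spiking": info, "rig_log": rig.log, "baseline_violations": violations}
        yield cell, rig.sweeps, cell_log


def generate_dcpsp_recordings(
    cells: list[CellRecord],
    proto: ProtocolSpec | None = None,
    spec: CohortSpec | None = None,
    seed: int = 0,
    templates: dict | None = None,
) -> dict[str, tuple[dict, dict]]:
    """Materialized dynamic-clamp recordings: cell id → (sweepsets, log)."""
    return {
        cell.cell_id: (sweeps, log)
        for cell, sweeps, log in iter_dcpsp_recordings(cells, proto, spec, seed, templates)
    }


# ---------------------------------------------------------------------------
# Membrane tests (voltage clamp QC sweeps)
# ---------------------------------------------------------------------------

def generate_membrane_tests(
    cells: list[CellRecord],
    seed: int = 0,
    noise_sd: float = 5.0,
    n_steps: int = 16,
    step: float = -5.0,
) -> dict[str, TimeSeries]:
    """Averaged membrane-test current responses per cell (16 hyperpolarizing
    steps, analytic circuit model plus white noise, averaged)."""
    out: dict[str, TimeSeries] = {}
    children = np.random.SeedSequence(seed).spawn(len(cells))
    for cell, child in zip(cells, children):
        rng = np.random.default_rng(child)
        clean = circuit_response(
            r_series=cell.r_series,
            r_input=cell.rc.r_mohm,
            capacitance=cell.rc.c_pf,
            step=step,
        )
        reps = clean.samples[None, :] + rng.normal(0.0, noise_sd, (n_steps, clean.n))
        out[cell.cell_id] = TimeSeries(reps.mean(axis=0), clean.dt, clean.t0, "pA")
    return out
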