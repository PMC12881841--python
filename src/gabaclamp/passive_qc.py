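"""Passive-property estimation from membrane-test sweeps and QC gating.

Recording quality is monitored from the averaged current response to small
hyperpolarizing voltage steps (−5 mV, 20 ms).  The estimator follows the
standard whole-cell membrane-test derivation for a pipette resistance R_s in
series with the parallel R_in ∥ C membrane:

* series resistance from the instantaneous current jump at the step onset,
  R_s = |ΔV| / |I(0⁺)|, with I(0⁺) taken from the exponential transient
  extrapolated back to the onset;
* input resistance from the steady-state current, R_in = |ΔV|/|ΔI_ss| − R_s;
* capacitance from the transient time constant τ = C·(R_s·R_in)/(R_s+R_in).

Inclusion gates: input resistance 410–1500 MΩ, compensated series resistance
7.9–30 MΩ, capacitance 5.7–30 pF; all bounds inclusive.  "Stable" properties
across an experiment are checked as a maximum relative drift between the
first and last membrane tests (default 20%; no published number exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import EstimationError, ParameterError
from .trace_model import TimeSeries

__all__ = [
    "PassiveProps",
    "QCGate",
    "QCResult",
    "circuit_response",
    "membrane_test",
    "qc_gate",
    "check_stability",
]


@dataclass
class PassiveProps:
    """Whole-cell passive/recording properties."""

    r_input: float  # MΩ
    r_series: float  # MΩ
    capacitance: float  # pF
    holding_current: float  # pA
    holding_potential: float  # mV

    def __post_init__(self) -> None:
        if min(self.r_input, self.r_series, self.capacitance) <= 0:
            raise ParameterError("resistances and capacitance must be positive")


@dataclass
class QCGate:
    """Inclusive acceptance ranges for recording inclusion."""

    r_input_range: tuple[float, float] = (410.0, 1500.0)
    r_series_range: tuple[float, float] = (7.9, 30.0)
    capacitance_range: tuple[float, float] = (5.7, 30.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.r_input_range, self.r_series_range, self.capacitance_range):
            if not lo < hi:
                raise ParameterError("each QC range needs low < high")


@dataclass
class QCResult:
    passed: bool
    reasons: list


def circuit_response(
    r_series: float,
    r_input: float,
    capacitance: float,
    step: float = -5.0,
    dt: float = 0.05,
    step_onset: float = 5.0,
    step_duration: float = 20.0,
    total: float = 30.0,
    holding_current: float = 0.0,
) -> TimeSeries:
    """Analytic current response of the R_s + (R_in ∥ C) circuit to a voltage
    step — the forward model behind :func:`membrane_test`.

    During the step: I(t) = ΔV/R_s·e^{−t/τ} + ΔV/(R_s+R_in)·(1−e^{−t/τ}) with
    τ = C·R_s·R_in/(R_s+R_in); the off transient is symmetric.  Currents in
    pA given mV and MΩ (factor 1000).
    """
    tau = capacitance * (r_series * r_input) / (r_series + r_input) / 1000.0  # ms
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    i = np.full(n, holding_current)

    def transient(trel, dv):
        i_inst = 1000.0 * dv / r_series
        i_ss = 1000.0 * dv / (r_series + r_input)
        return i_ss + (i_inst - i_ss) * np.exp(-trel / tau)

    on = (t >= step_onset) & (t < step_onset + step_duration)
    i[on] += transient(t[on] - step_onset, step)
    off = t >= step_onset + step_duration
    # after step release the charge on C relaxes back: equal and opposite jump
    i[off] += -transient(t[off] - step_onset - step_duration, step) + 1000.0 * step / (
        r_series + r_input
    )
    return TimeSeries(i, dt, 0.0, unit="pA")


def membrane_test(
    avg_current: TimeSeries,
    step: float = -5.0,
    step_onset: float = 5.0,
    step_duration: float = 20.0,
    holding_potential: float = -65.0,
) -> PassiveProps:
    """Estimate R_s, R_in and C from an averaged membrane-test response.

    The transient is fitted with a monoexponential (amplitude, τ) over the
    step interval; its back-extrapolation to the onset gives the
    instantaneous current for R_s, the final quarter of the step gives the
    steady state for R_in, and τ with both resistances gives C.
    """
    if step == 0:
        raise EstimationError("zero-amplitude step: no excursion to measure")
    t, i = avg_current.times, avg_current.samples
    pre = i[t < step_onset]
    if pre.size < 3:
        raise EstimationError("no pre-step samples for the holding current")
    holding = float(np.mean(pre))

    on = (t >= step_onset) & (t < step_onset + step_duration)
    t_on, i_on = t[on] - step_onset, i[on] - holding
    ss_mask = t_on >= 0.75 * step_duration
    di_ss = float(np.mean(i_on[ss_mask]))
    if di_ss == 0:
        raise EstimationError("no steady-state current excursion")

    y = i_on - di_ss  # decaying transient, sign of the step
    peak_k = int(np.argmax(np.abs(y[: max(3, y.size // 4)])))
    y_fit, t_fit = y[peak_k:], t_on[peak_k:]
    a0 = y_fit[0]
    if abs(a0) < 1e-9:
        raise EstimationError("no resolvable capacitive transient")
    k_e = int(np.argmin(np.abs(np.abs(y_fit) - abs(a0) / np.e)))
    tau0 = max(t_fit[k_e] - t_fit[0], avg_current.dt)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-(tt - t_fit[0]) / tau),
            t_fit,
            y_fit,
            p0=(a0, tau0),
            maxfev=10000,
        )
    except RuntimeError as e:  # pragma: no cover - pathological input
        raise EstimationError(f"transient fit failed: {e}") from None
    a_fit, tau_fit = popt
    if tau_fit <= 0:
        raise EstimationError("non-positive transient time constant")
    i_onset = a_fit * np.exp(t_fit[0] / tau_fit) + di_ss  # back-extrapolated to t=0⁺

    r_series = abs(1000.0 * step / i_onset)
    r_total = abs(1000.0 * step / di_ss)
    r_input = r_total - r_series
    if r_input <= 0:
        raise EstimationError("steady-state current implies non-positive input resistance")
    capacitance = 1000.0 * tau_fit * (r_series + r_input) / (r_series * r_input)
    return PassiveProps(
        r_input=float(r_input),
        r_series=float(r_series),
        capacitance=float(capacitance),
        holding_current=holding,
        holding_potential=holding_potential,
    )


def qc_gate(p: PassiveProps, gate: QCGate | None = None) -> QCResult:
    """Pass iff every property lies inside its inclusive range; the reasons
    list enumerates the violated gates."""
    gate = gate or QCGate()
    reasons = []
    for name, value, (lo, hi) in (
        ("r_input", p.r_input, gate.r_input_range),
        ("r_series", p.r_series, gate.r_series_range),
        ("capacitance", p.capacitance, gate.capacitance_range),
    ):
        if not lo <= value <= hi:
            reasons.append(name)
    return QCResult(passed=not reasons, reasons=reasons)


def check_stability(
    first: PassiveProps, last: PassiveProps, max_rel_drift: float = 0.2
) -> bool:
    """Series resistance and capacitance drift between the first and last
    membrane tests must stay within ``max_rel_drift`` (relative)."""
    drifts = (
        abs(last.r_series - first.r_series) / first.r_series,
        abs(last.capacitance - first.capacitance) / first.capacitance,
    )
    return all(d <= max_rel_drift for d in drifts)
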