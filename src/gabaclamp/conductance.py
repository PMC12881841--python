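"""GABA conductance templates, the dynamic-clamp current law, and the
monoexponential decay fit.

The simulated synaptic conductance is a step-to-peak monoexponential,

    g_syn(t) = g_max · exp(−t/τ)   for t ≥ 0,   g_syn(t) = 0 for t < 0,

with t = 0 at the stimulus trigger.  The command current injected by the
dynamic clamp is the conductance times the linear driving force,

    I_dc = g_syn · (Vm − E_rev),

negative (inward, depolarizing) whenever Vm sits below the GABA-A reversal
potential.  The default library ships the eight study conditions: g_max ∈
{1, 2, 5, 10} nS crossed with τ ∈ {7, 10} ms at E_rev = −36.5 mV.

Decay kinetics of both recorded PSCs and simulated transients are summarised
by a single-parameter exponential fitted between the 80% and 20% crossings of
the normalized peak, the only free parameter being τ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DataError, ParameterError, WindowError
from .trace_model import TimeSeries

__all__ = [
    "ConductanceTemplate",
    "DecayFit",
    "make_template",
    "default_template_library",
    "dynamic_clamp_current",
    "fit_decay_tau",
]

E_GABA_MV = -36.5


@dataclass
class ConductanceTemplate:
    """A sampled monoexponential conductance waveform with its parameters."""

    g_max: float  # nS
    tau: float  # ms
    e_rev: float  # mV
    duration: float  # ms
    dt: float  # ms
    g_syn: TimeSeries  # nS, t0 = 0 at trigger
    template_id: str = ""

    def conductance_at(self, t) -> np.ndarray:
        """Analytic g_syn(t); zero before the trigger (t < 0)."""
        t = np.asarray(t, dtype=float)
        g = np.where(t >= 0.0, self.g_max * np.exp(-np.maximum(t, 0.0) / self.tau), 0.0)
        return g if g.ndim else float(g)


def make_template(
    g_max: float,
    tau: float,
    e_rev: float = E_GABA_MV,
    dt: float = 0.1,
    duration: float = 100.0,
    template_id: str | None = None,
) -> ConductanceTemplate:
    """Sample g_max·exp(−t/τ) on [0, duration] at spacing ``dt``.

    ``duration`` must cover at least five decay time constants so the sampled
    waveform has decayed below 1% of peak.
    """
    if g_max <= 0 or tau <= 0 or dt <= 0:
        raise ParameterError("g_max, tau and dt must be positive")
    if duration < 5.0 * tau:
        raise ParameterError("duration must be at least 5·tau")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    g = g_max * np.exp(-t / tau)
    tid = template_id or f"g{g_max:g}_tau{tau:g}"
    return ConductanceTemplate(
        g_max=g_max,
        tau=tau,
        e_rev=e_rev,
        duration=duration,
        dt=dt,
        g_syn=TimeSeries(g, dt, 0.0, unit="nS"),
        template_id=tid,
    )


def default_template_library() -> dict[str, ConductanceTemplate]:
    """The packaged eight-condition template library, keyed by template id."""
    cfg = json.loads(
        resources.files("gabaclamp.data").joinpath("templates.json").read_text()
    )
    lib: dict[str, ConductanceTemplate] = {}
    for entry in cfg["templates"]:
        lib[entry["id"]] = make_template(
            g_max=entry["g_max_nS"],
            tau=entry["tau_ms"],
            e_rev=cfg["e_rev_mV"],
            dt=cfg["dt_ms"],
            duration=cfg["duration_ms"],
            template_id=entry["id"],
        )
    return lib


def dynamic_clamp_current(vm, g, e_rev: float = E_GABA_MV):
    """Command current g·(Vm − E_rev) in pA (g in nS, potentials in mV).

    Total function: accepts scalars or arrays and broadcasts.  The sign
    convention matches the membrane update, whose leading minus turns this
    negative (inward) current into a depolarization when Vm < E_rev.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ParameterError("conductance must be non-negative")
    out = g * (np.asarray(vm, dtype=float) - e_rev)
    return out if out.ndim else float(out)


@dataclass
class DecayFit:
    """Result of the 80→20% single-parameter exponential decay fit."""

    tau_hat: float  # ms
    fit_window: tuple[float, float]  # (t_80, t_20) ms, relative to the peak
    residual_rms: float  # on the magnitude-normalized trace

    def __post_init__(self) -> None:
        t80, t20 = self.fit_window
        if not (t80 < t20):
            raise WindowError("fit window must have t_80 < t_20")
        if not self.tau_hat > 0:
            raise ParameterError("tau_hat must be positive")


def _first_crossing_after(t: np.ndarray, m: np.ndarray, start: int, level: float) -> float:
    """First time after index ``start`` where ``m`` falls below ``level``,
    linearly interpolated between the bracketing samples."""
    below = np.nonzero(m[start + 1 :] < level)[0]
    if below.size == 0:
        raise WindowError(f"trace never decays below {level:.0%} of peak")
    k = start + 1 + below[0]
    frac = (m[k - 1] - level) / (m[k - 1] - m[k])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def fit_decay_tau(
    trace: TimeSeries,
    peak_index: int | None = None,
    peak_value: float | None = None,
) -> DecayFit:
    """Fit exp(−t/τ) to the decay of a transient between its 80% and 20%
    crossings.

    The trace is normalized to unit peak magnitude and time is re-origined at
    the peak, so the fitted model has fixed amplitude and τ is the only free
    parameter.  Either polarity is accepted: the fit operates on the
    magnitude-normalized trace.  The loss is unweighted least squares over all
    samples whose time (relative to the peak) lies inside the interpolated
    80%→20% window; τ is found by bounded scalar minimization.

    ``peak_value`` overrides the normalization constant (by default the sample
    at ``peak_index``); callers averaging noisy events can pass a lower-noise
    peak estimate, since a biased normalization biases the fitted τ.
    """
    v = trace.samples
    if not np.all(np.isfinite(v)):
        raise DataError("trace contains non-finite samples")
    if peak_index is None:
        peak_index = int(np.argmax(np.abs(v)))
    peak = v[peak_index] if peak_value is None else peak_value
    if peak == 0.0:
        raise DataError("zero peak amplitude; nothing to normalize")
    m = v / peak  # magnitude-normalized: m[peak_index] == 1, decays toward 0
    t = (np.arange(trace.n) - peak_index) * trace.dt

    t80 = _first_crossing_after(t, m, peak_index, 0.8)
    t20 = _first_crossing_after(t, m, peak_index, 0.2)
    in_window = (t >= t80) & (t <= t20)
    tw, mw = t[in_window], m[in_window]
    if tw.size < 2:
        raise WindowError("fewer than two samples inside the 80–20% window")

    window_len = t20 - t80

    def sse(tau: float) -> float:
        r = mw - np.exp(-tw / tau)
        return float(r @ r)

    res = minimize_scalar(
        sse,
        bounds=(1e-6, 10.0 * window_len),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau_hat = float(res.x)
    rms = float(np.sqrt(sse(tau_hat) / tw.size))
    return DecayFit(tau_hat=tau_hat, fit_window=(t80, t20), residual_rms=rms)
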