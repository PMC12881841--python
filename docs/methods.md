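# Methods

## The model

`gabaclamp` reproduces, in software, the computational chain of a
dynamic-clamp experiment on GnRH neurons.  A simulated GABA_A synaptic
conductance

    g_syn(t) = g_max · exp(−t/τ),   t = 0 at the trigger,

drives a command current through the linear driving force

    I_dc = g_syn(t) · (V_m − E_rev),

with E_rev = −36.5 mV, the GABA_A reversal potential under the elevated
intracellular chloride these neurons maintain.  The packaged template library
crosses g_max ∈ {1, 2, 5, 10} nS with τ ∈ {7, 10 ms} — the prepubertal and
adult decay constants — at a 0.1 ms sampling interval.

The membrane is a passive RC circuit integrated by explicit forward Euler:

    ΔV = −(Δt/C) · (I_syn + I_leak − I_inj),    I_leak = g_leak (V − E_leak),

with g_leak = 1/R, R = 737 MΩ (the mean input resistance of the recorded
population), E_leak = −65 mV, Δt = 0.1 ms, and capacitance swept over
8–16 pF in 2 pF steps for the in-silico capacitance study.  Units are fixed
package-wide as mV / pA / nS / pF / MΩ / ms, under which the membrane
equation is dimensionally closed (nS·mV = pA; pA·ms/pF = mV).

### Numerical accuracy of the integrator

Forward Euler at Δt = 0.1 ms is retained in the measurement path because it
is the in-silico method being modelled, not because it is the most accurate
choice.  Its deviation from the exact solution scales linearly with Δt and
reaches ~0.7 mV at the largest conductance (10 nS, 8 pF) near the
conductance onset, where dV/dt ≈ 30 mV/ms; at Δt = 0.01 ms the worst case is
below 0.1 mV.  The exact reference, `closed_form_rc`, is an exponential
integrator built on the integrating factor exp(A(t)) with the analytic
conductance integral ∫g_syn = g_max·τ·(1 − e^{−t/τ}); the forcing term is
integrated per step with 5-point Gauss–Legendre quadrature, making its own
error negligible (≪ 1e-9 mV).  It exists for verification only.  Tests
assert the linear convergence of the Euler path onto this oracle.

## Decay fitting (PSCs and templates)

Decay kinetics are summarised by a single-parameter exponential fitted
between the 80% and 20% crossings of the normalized peak: the trace is
normalized to unit peak magnitude, time is re-origined at the peak, crossing
times are linearly interpolated, and an unweighted least-squares fit of
exp(−t/τ) over the in-window samples varies only τ (bounded scalar
minimization on τ ∈ (0, 10 × window length], relative tolerance 1e-9).
Either polarity is accepted; the fit is scale invariant.

For *averaged PSCs* the normalization constant matters: a single noisy
sample is a biased peak estimate (peak alignment selects positive noise, and
a finite rise time depresses the peak below the back-extrapolated decay),
and a biased normalization propagates directly into a biased τ.  The
averaging step therefore re-anchors the scale on the decay itself: for each
candidate τ the best-fitting scale is the projection of the average onto
exp(−t/τ) over the current 80–20% window, and the window is re-derived from
the re-anchored normalization until self-consistent.  The reported fit still
varies only τ with the amplitude fixed at the converged normalization.  On
noiseless synthetic trains this recovers the generating τ to < 0.1%; without
re-anchoring the bias is 1–4%.

A second bias worth documenting: the per-event baseline window must end well
before the rising phase (default 2.5 ms before the aligned peak).  Alignment
jitter otherwise lets rise-phase samples leak into the baseline, which
subtracts into the decay as an offset and reads as a ~1–2% faster τ.

## Event detection and isolation

The event detector is deliberately plain — boxcar smoothing (0.5 ms),
prominence-gated local extrema, amplitude re-measured against the preceding
5 ms baseline with a 1 ms guard, sub-sample peak interpolation — because the
original study does not describe its detector.  It is validated only against
the synthetic generator (recall ≥ 95%, false-positive rate ≤ 5% at noise SD
= min_amplitude/5) and makes no claim of reproducing original event counts.
Isolation keeps events at least 50 ms (inclusive) from both neighbouring
peaks; 5–40 isolated events are averaged per cell, the earliest 40 when more
are available (a deterministic choice; the study states only the range).

## dcPSP analysis

Sweeps qualify for subthreshold averaging only with a stable baseline inside
−66.5…−63.5 mV for the 10 ms before the trigger.  (The source protocol
prints −66.5 in one place and −66.6 in another; −66.5 is used and the range
is configurable.)  Stability is a peak-to-peak excursion ≤ 1 mV over the
window — no published tolerance exists, so the value is a package default
chosen so that realistic recording noise (~0.15 mV SD) passes almost always.
A minimum of five qualifying AP-free sweeps is required before averaging.
Features on the average: baseline (10 ms pre-trigger mean), latency
(trigger → interpolated peak), amplitude (baseline → peak), and the 80/20
decay time (interpolated falling-phase crossings).  All are
baseline-relative and hence invariant to constant offsets.

## Action-potential metrics

Threshold is defined by the membrane potential's second derivative exceeding
10,000 V/s/s — converted once to 10 mV/ms².  The criterion's units are those
of a second derivative, so the detector tests the second derivative's value
(a literal "slope of the second derivative" reading would be a third
derivative and dimensionally inconsistent with the stated units).  Three
implementation details:

* **Sustained crossing** (`min_run`, default 2 samples): the conductance
  step at the trigger creates a one-sample artifact in the discrete second
  difference (slope jumps by up to ~30 mV/ms in one Δt).  Requiring
  consecutive samples above criterion rejects it; a genuine upstroke stays
  above criterion for several samples.
* **Sub-sample onset refinement**: when the true threshold lies between
  samples, the first supra-criterion second difference uses a stencil only
  partially on the spike; modelling the onset as a curvature jump and
  solving for the sub-sample offset recovers threshold time to ~0.005 ms
  (median) instead of up to one sample early.
* **Smoothed path for noisy sweeps**: white noise of 0.15 mV SD maps to
  ~36 mV/ms² RMS in the raw two-sample second difference at Δt = 0.1 ms —
  far above the criterion.  Classification therefore estimates curvature
  with a Savitzky–Golay fit (window 1.5 ms, order 3; noise ≈ 0.5 mV/ms²)
  and opens its search window 1 ms after the trigger, past the smeared
  onset artifact.  Precision measurements on clean fixtures use the raw
  path.

Amplitude is threshold → peak; rate of rise is max dV/dt on that interval;
FWHM is measured at threshold + amplitude/2 with interpolated crossings; AHP
time and amplitude are measured relative to threshold at the post-peak
minimum (search window 20 ms, covering all reported AHP times).  Only the
first AP per sweep is measured.  A spike whose threshold falls after the
peak of the cell × condition's AP-free averaged dcPSP is *delayed*; when
fewer than five clean sweeps exist the reference latency falls back to the
mean of whatever AP-free sweeps there are, and with none the classification
is deferred with an explicit flag.

Note: the rate-of-rise magnitudes printed in the source tables (~0.4 mV/ms)
are orders of magnitude below typical somatic AP upstrokes; the
implementation computes max dV/dt as defined (yielding ~10² mV/ms on the
stereotyped spikes) and does not attempt to match those magnitudes.

## Passive properties and QC

The membrane test estimates R_s from the back-extrapolated instantaneous
current of the step transient, R_in from the steady state, and C from the
transient time constant τ = C·R_s R_in/(R_s+R_in) — the standard whole-cell
derivation, since the original estimation method is unreported.  It is
validated against the analytic two-resistor+capacitor forward model (3%
recovery; feeding estimates back through the model reproduces the trace to
< 2% RMS).  Inclusion gates are inclusive intervals: R_in 410–1500 MΩ,
R_s 7.9–30 MΩ, C 5.7–30 pF.  "Stable" properties are checked as ≤ 20%
relative drift between first and last membrane tests (configurable; no
published number).

## The synthetic cohort

The generator emulates the study's two-by-two design (3-week vs adult ×
vehicle vs prenatally androgenized).  Per-group passive parameters are drawn
from truncated normals with the published group means and SEM-derived SDs
(SD = SEM·√n with the per-group n), truncated to the QC ranges so generated
cells pass QC unless violations are injected.  PSC decay constants use the
age-class parameters 7.4 ms (SEM 0.13, n = 11) and 9.9 ms (SEM 0.25,
n = 12); PSC amplitudes have no group effect (30 ± 8 pA, a package choice —
no amplitude is printed).  Current noise on PSC sweeps defaults to 2 pA SD
and voltage noise on dynamic-clamp sweeps to 0.15 mV SD, values typical of
low-noise whole-cell recordings.

Firing structure is qualitative, matching the published response tables in
ordering rather than estimating unidentifiable per-sweep probabilities: no
cell fires at 1 or 2 nS; 5 nS firing concentrates in 3-week controls; 10 nS
recruits every group, most in 3-week controls; responders fire on a per-sweep
probability drawn U(0.2, 1.0) (the reported 2–10 of 10 traces); delayed
spikes occur only in 3-week PNA cells at 10 nS.  These defaults are labelled
illustrative.

Two deliberate departures from biology, imposed by the RC abstraction:

* **Spike thresholds.**  A passive membrane driven by ≤ 10 nS from −65 mV
  asymptotes to −39.9 mV and peaks near −42…−50 mV, so biological thresholds
  cannot always be crossed.  The rig splices a stereotyped AP waveform
  (half-cosine rise and fast fall realizing the requested FWHM, a slow dip
  reaching the AHP minimum at the requested time, then a slope-matched
  critically-damped relaxation back onto the passive trace) at the crossing
  of a per-cell threshold placed just below the cell's own subthreshold peak
  (margin U(0.5, 2) mV).  Ground truth for every splice is recorded in the
  manifest.  Feature-recovery validation instead uses standalone fixtures
  whose underlying ramp crosses thresholds spanning the full reported range
  (−52…−39 mV).
* **Holding currents.**  In a pure RC cell held at E_leak = −65 mV the
  analytic holding current is ≈ 0, not the tens of pA reported for real
  cells (whose resting potential sits above the holding target).  The
  generator keeps E_leak = −65 mV and records the computed holding current;
  no downstream gate depends on it.

What passing the synthetic closure therefore shows: the pipeline's gates,
classification, averaging and feature definitions are mutually consistent
and recover known ground truth under realistic noise.  What it does not
show: performance on real recordings with drift, access-resistance changes,
synaptic barrages, or non-stereotyped spike shapes.

## Statistics

Shapiro–Wilk (α = 0.05) gates mean ± SEM vs median ± IQR reporting.  Group
comparisons use a two-way ANOVA over age × treatment with type-III sums of
squares and sum-to-zero coding (the convention of the graphing software the
original tables reflect; the sum-of-squares type is not stated there), with
Šídák-adjusted pairwise p-values for the four reported contrasts computed
from the pooled residual variance.  Welch's unequal-variance t-test carries
Satterthwaite degrees of freedom.  On balanced designs the ANOVA reduces
exactly to the classical closed-form decomposition, which serves as the test
oracle.  Response tables count cells as PSP (no sweep spiked), AP (all
non-excluded sweeps spiked) or Both, with percentages recomputed from
counts.

## Problem sizes and determinism

Default protocol sweeps are 0.5 s pre-trigger + 3 s post-trigger at 0.1 ms
(the final protocol; the 5.5 s variant is available via configuration), ten
repetitions per template, eight templates.  Cohort runs stream cell by cell;
a 48-cell cohort at full protocol length analyses in well under a minute.
Test-suite simulations use shorter windows (the RC transient settles within
~150 ms) — the physics is unchanged.  Every stochastic component draws from
an explicit seed; fixed seeds give bit-identical sweeps and manifests.

## Known limitations

* The RC membrane omits all voltage-gated conductances; the interpretive
  questions of the underlying biology (potassium-current differences, AIS
  location) are out of scope.
* The event detector is plumbing, not a contribution; deconvolution or
  template-matching detectors would outperform it on real data.
* Loop-delay emulation is a fixed delay (default 0, optionally one sample or
  the measured 21.29 µs); loop jitter is not modelled.
* The capacitance estimator is an offline fit and is not claimed to match
  amplifier compensation-dial readouts.
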