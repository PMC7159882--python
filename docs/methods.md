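# Methods

## Scope and data flow

The package reproduces a quantitative chain from oocyte voltage-clamp
dose–response characterization of PUFA-analogue effects on three cardiac
channel complexes (Kv7.1/KCNE1 → IKs, Cav1.2/β3/α2δ → ICaL, Nav1.5/β1 →
INa) to ventricular action-potential predictions. The original recordings
are not redistributed; a synthetic-data module generates current families
with the statistical structure the analysis assumes, and a fixture library
carries the published per-compound effect values the simulations use.

## Synthetic voltage clamp (`cardiopufa.synth`)

**Protocols.** The generator emits the recording protocols verbatim: IKs —
hold −80 mV, prepulse −140 mV (500 ms), test steps −100…+60 mV in 20 mV
increments (2 s), tail −20 mV; Nav activation −90…+40 mV (10 mV); Nav
availability — 500 ms prepulses −140…−30 mV, test −30 mV; Cav activation
−70…+40 mV; Cav availability — prepulses −80…+20 mV, test +10 mV.

**Current model.** The analysis only consumes steady-state and peak
quantities, so gating is single-exponential with fixed,
concentration-independent time constants (IKs activation τ = 750 ms,
deactivation τ = 150 ms; Nav rise/decay 0.2/1 ms; Cav 2/150 ms). The IKs
open probability relaxes toward a Boltzmann `Po(V)` (control V½ = +25 mV,
s = 17.5 mV, the fitted control slope); tails deactivate exponentially
toward the −20 mV steady level, which makes the measured tail G–V an affine
image of `Po(V)` — midpoint and slope are preserved exactly and conductance
ratios are unbiased, regardless of the truncation of the 2 s step. Nav/Cav
sweeps share one normalized transient shape, so the sampled peak equals the
closed form `g·a∞(V)·(V−Erev)` (activation) or
`g·h∞(Vpre)·a∞(Vtest)·(Vtest−Erev)` (availability) exactly at zero noise.
A single activation Boltzmann stands in for `m³`-type kinetics because all
peak curves are normalized before comparison. Noise is additive i.i.d.
Gaussian on every sample (the recordings' noise spectrum is not
characterized; 5 kHz default sampling for TEVC). Optional per-oocyte
variability multiplies a family's conductance by one lognormal draw
(σ = 10% when enabled; off by default).

**Concentration dependence.** The published dose curves exist as figures
only; the text prints complete effect sets at 7 µM and the dose–response
table gives Km of I/I0 per compound/channel. The generator therefore
Hill-parameterizes every observable with the channel's tabulated Km
(a 40 µM placeholder where the table prints ">20", flat where the 7 µM
effect is non-significant) and a saturating amplitude solved so the curve
passes exactly through the printed 7 µM value with n = 1. Where that
n = 1 curve would extrapolate past full block (for the strong INa blockers
the printed pair {I/I0(7 µM), Km} implies a saturation below zero), the
saturation is pinned at full block and the Hill coefficient is solved
instead — the anchor stays exact and the curve stays physical. Effects
reported non-significant are represented as identity so simulations do not
inject noise-level parameter changes (`include_ns=True` overrides).

**Calcium transients.** Fluorescence records are sums of
`A·(1−e^{−t/τ_rise})·e^{−t/τ_decay}` transients at jittered spontaneous
beat times plus Gaussian noise (defaults: period 1.25 s, jitter σ 50 ms,
τ_rise 60 ms, τ_decay 170 ms, 1 kHz sampling — an APD90 near 500 ms,
matching the monolayer scale). True beat times and the analytic
(root-finding) per-transient APD90 ship as ground-truth metadata.

## Dose–response analysis (`cardiopufa.tevc`, `.boltzmann`, `.hill`)

Tail G–V values are window means (default 5–25 ms into the tail) relative
to the post-tail baseline, on the raw scale so Gmax ratios remain
meaningful. Boltzmann fits use four free parameters with the slope sign
free (availability curves fit with s < 0); initialization comes from the
curve extrema and the midpoint crossing, with five jittered restarts before
a failure is flagged — never silently. Gmin is free by default; a
constrained (Gmin = 0) mode exists because the original fitting convention
is not stated. ΔV½ is the difference of fitted midpoints; the conductance
effect is the ratio of fitted (Gmax−Gmin) spans. I/I0 uses the 0 mV
activation-protocol step (end-of-step steady state for IKs, signed peak for
Nav/Cav; which 0 mV pulse the original analysis used is not stated, so this
is configurable). Hill fits bound A ≥ −1, report adjusted R², and flag
fitted Km beyond the largest tested concentration as ">Cmax" rather than a
point estimate. Exact ties in peak detection resolve to the first sample in
time. SEM is computed across replicate families ("oocytes").

Verified recovery (noiseless): ΔV½ to ≤ 0.5 mV, conductance ratios to ≤ 1%,
Km to ≤ 2%; at 2% amplitude noise, 100-seed Monte-Carlo medians stay within
2 SEM of truth (the SEM of the estimator ensemble).

## The myocyte model (`cardiopufa.ord`)

The O'Hara–Rudy dynamic human ventricular model was transcribed in full:
41 states, all sarcolemmal currents (INa fast/late with CaMK-phosphorylated
fractions, Ito, ICaL/ICaNa/ICaK with subspace calcium, IKr, IKs, IK1,
INaCa in bulk and subspace, INaK, background and pump currents), SR release/
uptake/translocation, calcium buffering, and the endo/epi/M conductance
scalings. The epicardial variant at steady 1 Hz pacing yields APD90 ≈
228 ms from this implementation, in the published range for the model.

**Modification hooks.** PUFA effects enter exclusively as (a) voltage
shifts applied to steady-state gate curves — IKs activation gates (xs1,
xs2), INa inactivation gates (h, j, and their phosphorylated and late-
component counterparts, per the assumption that the late current shares the
shift), optionally ICaL inactivation — and (b) multiplicative factors on
GKs, GNa+GNaL, PCa and GKr. Time constants are never altered. Composition
is exact: factors multiply, shifts add.

**Numerics.** The right-hand side is one numba-compiled core that exposes
each Hodgkin–Huxley gate as a (steady state, time constant) pair. Pacing
uses hybrid Rush–Larsen (exact exponential gate updates) with forward Euler
for voltage and concentrations: Δt = 2.5 µs inside a 20 ms
stimulus/upstroke window, 5 µs elsewhere, Vm recorded at 0.1 ms. A
three-level refinement study put the residual APD90-percent-change error of
these defaults near 0.03 percentage points. The same right-hand side runs
under scipy's adaptive BDF solver (rtol 1e−6, atol 1e−8) as an independent
numerical route; steady-state APD90 agrees within 0.2 ms, and the test
suite enforces < 1 ms. No reference ORd implementation is available in
this environment, so this cross-check validates the integration, not the
transcription; the transcription is constrained by the published resting,
upstroke and APD characteristics and by the block/shortening experiments
below.

**Protocols and metrics.** Square-pulse stimulus −80 µA/µF for 0.5 ms
(assigned to the K+ balance as in the model definition). Steady state is
declared when consecutive-beat APD90 differs by < 0.1 ms (minimum 20
beats), capped at 400 conditioning beats; both the criterion and the beats
used are reported. APD90 runs from the maximum-upstroke-velocity time to
the first crossing of `V90 = Vpeak − 0.9(Vpeak − Vrest)` with linear
interpolation, Vrest taken immediately pre-stimulus. "No action potential"
means Vm fails to reach 0 mV within 50 ms of the stimulus — a flag, not an
exception, since sodium-channel block is expected to produce exactly this.
An EAD is a negative-to-positive dVm/dt reversal after the peak at
Vm > −40 mV followed by ≥ 2 mV net depolarization; reversals within 50 ms
of the upstroke are excluded because the epicardial phase-1 notch/dome is a
reversal but not an afterdepolarization.

**Dofetilide surrogate.** The drug is modelled as fractional IKr block at
slow pacing (CL 4000 ms). The block fraction is configurable; the default
is 92.5% because, in this implementation of the epicardial cell, EAD
induction requires > 90% block (85% merely prolongs the AP). At the
default, the protocol yields one EAD per beat at steady state, and the 7 µM
DHA-glycine modification set suppresses it completely.

## Calcium-transient analysis (`cardiopufa.cat`)

Detection runs on the zero-phase low-pass-filtered signal (100 Hz default,
mirroring the acquisition filter): onsets are upward crossings of
baseline + 0.2 × amplitude with hysteresis (re-arm at half threshold) and a
0.4 s refractory period; the baseline is a rolling minimum whose window
(default 2.5 s) must exceed one beat period, otherwise it rides up the
decaying transient tail. CaT APD90 runs from the detected onset to the
first decay-phase crossing of baseline + 0.10 × (peak − baseline), linearly
interpolated; beats truncated by the record end are dropped. The operational
onset (a threshold crossing) trails the true transient onset by a fixed,
shape-dependent lag, so validation compares against a root-finding oracle
that applies the same operational definitions to the closed-form transient:
agreement is within one sample at zero noise, and a 100-seed sweep at 2%
noise finds every true beat with no spurious detections. Fridericia
correction divides APD90 by the cube root of the forward RR interval in
seconds (the last beat reuses the preceding interval). Monolayer summaries
average the first ten complete beats, then mean ± SEM across monolayers
with paired control/treated deltas.

What passing these tests shows — and does not. The synthetic records have
exponential transients, stationary baselines and white noise; real
monolayer recordings add photobleaching drift, motion artifacts and
non-stationary beat shapes that the generator does not emulate, so pipeline
accuracy on real data is bounded below by these results, not established by
them. The published monolayer APD90c values themselves require the original
optical recordings and are out of scope.

## Simulation experiments (`analysis/04`, acceptance)

With the epicardial model at the defaults above: scaling GKr to 75% of
control prolongs steady-1 Hz APD90 by ≈ 41 ms; the 7 µM DHA-glycine set
shortens APD90 by ≈ 5.0/5.0/5.0% at 40/60/200 bpm, with the 40- and
200-bpm magnitudes marginally exceeding the 60-bpm one and the
end-diastolic xs1 occupancy rising from 0.25 (60 bpm) to 0.60 (200 bpm) —
the rate-dependent IKs accumulation that underlies the fast-rate effect.
The four broadly-blocking taurine analogues at 7 µM (INa conductance scaled
by their printed 0 mV current ratios 0.1/0.2/0.5/0.07 with the printed
inactivation shifts) all produce the no-action-potential flag at 60 bpm.
The non-monotonic 40-vs-60 bpm ordering is reported, not explained.

## Known limitations

- Channel kinetics in the generator are deliberately minimal; it cannot be
  used to study activation/inactivation kinetics, only steady-state/peak
  observables.
- The concentration-dependence truths interpolate a single-Km Hill family
  through one measured point per observable; real dose curves need not be
  Hill-shaped nor share Km across observables.
- The myocyte model carries the known idealizations of its family (high
  plateau, simplified IKr gating); no tissue coupling, no hiPSC-CM
  electrophysiology model.
- Dofetilide is a pure conductance factor: no state-dependent or
  use-dependent binding.
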