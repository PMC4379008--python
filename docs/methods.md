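# Methods

This note documents the models, calibrations and numerical choices behind
`melstep`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and where genuinely open design
decisions were settled.

## Spectral model

Spectra are sampled functions on a uniform wavelength grid, 300–780 nm at
1 nm by default (the usual spectroradiometer convention; the grid is
configurable). Pigment sensitivities come from the Govardovskii A1 template:
an alpha band

    S(x) = 1 / (e^{A(a-x)} + e^{B(b-x)} + e^{C(c-x)} + D),   x = λmax/λ

with A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and
a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940), plus a Gaussian beta band of
amplitude 0.26 centred at 189 + 0.315·λmax with width −40.5 + 0.195·λmax.
The sum is renormalised so the grid point nearest λmax is exactly 1.
Default peaks are the standard mouse values, rod 498 nm and melanopsin
480 nm; both are arguments, not constants.

In-vivo sensitivities are multiplied by a lens transmission curve before
renormalisation. The built-in template is a logistic short-wavelength cut,
T(λ) = 1/(1+exp(−(λ−360)/12)) — near-full transmission through the visible
range with a soft UV roll-off — and can be replaced by any measured
two-column CSV. In-vitro (isolated retina) sensitivities omit the
correction.

Pigment-effective photon flux is the trapezoidal integral of spectrum ×
sensitivity; trapezoidal quadrature is exact for the piecewise-linear
representation of sampled spectra, and agrees with a 100×-refined-grid
computation to well under 0.1 % for smooth LED spectra. Neutral density d
multiplies flux by 10^(−d); ND composes additively and subtracts exactly
from log10 flux. Retinal-to-corneal conversion multiplies by pupil
area/retinal area, 0.5 for a fully dilated mouse pupil.

## Silent substitution

With two primaries the rod-silent step is the solution of a 2×2 linear
system: the step's rod-effective flux equals the background's, and its
melanopsin-effective flux equals background × (1+c)/(1−c) for Michelson
contrast c = (step − background)/(step + background). The system is solved
in closed form; feasibility is a box constraint (each drive weight in
[0, max_drive], default 1). Solver tolerances — residual silenced contrast
≤ 1e−9, target contrast error ≤ 1e−6 — are numerical-precision guarantees,
not physiological claims.

The maximum achievable silent contrast is computed exactly: the
isoluminance constraint confines step weights to a line segment inside the
gamut box, target flux is linear along that segment, so the optimum sits at
an endpoint. Tests cross-check this against a 10⁴-point grid search.

The LED fixture is synthetic (measured spectra for the original hardware
are not published): Gaussians at 438 nm ("blue") and 575 nm ("yellow").
The bandwidth default is 18 nm FWHM. This was chosen over a broader 25-nm
Gaussian because, against the rod/melanopsin templates above, 25-nm bands
cap the rod-silent melanopsin contrast at 69.9 % — just below the 71 % top
of the contrast series the protocols require — whereas 18-nm bands reach
72.1 % (a 6.2-fold melanopsin excursion) with working headroom. Primaries
are normalised to equal rod-effective flux at unit drive, and scaled so the
default background (yellow at half drive, ND0) delivers 10^14.3
melanopsin-effective photons/cm²/s — a daylight-range background.

Rod-contrast control stimuli (melanopsin silenced, rod stepped at 4/15/30 %)
are solved from a *blue* background with yellow flashes. From a pure-yellow
background a positive rod contrast would require negative blue drive; the
blue-background geometry is also what the original calibration experiments
used.

A per-preparation `blue_gain` factor (default 1.0) rescales the blue weight
of the solved step, mirroring the small (<4 %) empirical LED adjustments
used to find *effective* isoluminance in a live preparation. It is applied
to the step only; which member the original online calibration adjusted is
not recorded, and the choice is inconsequential for the contrast
bookkeeping, which is always recomputed from the final weights.

## Protocols

Protocols are gap-free epoch tilings; all randomisation (trial interleaving,
dark inter-pulse intervals) is a seeded Fisher–Yates shuffle / uniform draw
from a `numpy` Generator, so identical seeds give bit-identical schedules.

* Steady-background steps: adaptation (default 600 s), then steps (30 s
  dLGN / 20 s retina) at several contrasts interleaved pseudo-randomly,
  ISI 210 s (dLGN) or 180 s (retina), ≥14 repeats.
* Ramp protocol: ND4→ND0→ND4 in 0.5-ND levels. Each level is one 240-s
  cycle — 200-s ramp (linear in optical density, hence exponential in
  flux), 10-s hold, 30-s step. The first level of each arm replaces the
  ramp slot with steady background so every cycle is a full 240 s; 18
  cycles give exactly 72 min for the up+down pair, flanked by 240-s
  adaptation epochs at ND4. Whether the original 72-minute figure shared
  the ND0 cycle between arms cannot be derived from its description; this
  decomposition is the one that reproduces the printed total and is
  documented as such, not asserted as the original intent.
* Calibration flicker: alternating blue flash / yellow background,
  50:200 ms (4 Hz) or 100:400 ms (2 Hz), default ND3.
* Dark-adapted blue pulses (10 s, 50–110-s seeded dark intervals) and a
  1-Hz, 50-ms rod-favouring yellow flash at ND3.

Trace rendering samples per-pigment flux on a uniform grid; ramps
interpolate ND linearly. Rod flux through a rod-silent step is constant by
construction (relative deviation ≤ 1e−9 is asserted, achieved at machine
precision).

## Synthetic units

The rate models are this package's own phenomenological constructions; the
source experiments report response shapes and statistics, not equations.
Defaults are calibrated so the analysis stage, run on the synthetic data,
lands in the reported regimes (Δ rate 1–2 Hz, threshold near 10^12
melanopsin photons/cm²/s, ≈1-log adaptation shift in vivo).

**Melanopsin pathway.** Threshold-linear drive on log irradiance,
`mel_gain · max(0, x − θ)` with x = log10 melanopsin flux, filtered by an
asymmetric first-order stage (τ_on rising, τ_off falling — responses decay
more slowly than they build). The adaptation state θ relaxes with time
constant `adapt_tau_s` toward θ_base + adapt_gain·(x̄ − θ_base), where x̄ is
an exponential running mean of the log flux floored at θ_base (adaptation
elevates the threshold after bright exposure but never sensitises below
base). Key defaults:

| parameter | default | meaning |
|---|---|---|
| `baseline_hz` | 5 | spontaneous rate |
| `mel_gain` | 2 Hz/log | drive per log unit above threshold; puts the 71 %-contrast step response at ≈1.4 Hz, inside the reported 1–2-Hz band |
| `mel_threshold_log` | 12.0 | absolute threshold (no responses below 10^12 photons/cm²/s) |
| `mel_tau_on_s` / `mel_tau_off_s` | 2.5 / 12 | step responses build within seconds and take >10 s to relax |
| `adapt_gain` | 0.6 (dLGN), 0 (retina) | fraction of the recent-light elevation passed to the threshold |
| `adapt_tau_s` | 700 s | adaptation memory; with the ramp's 0.5 ND/240 s slope this lags ≈1.4 log units |

With these values the down-arm detection threshold on the ramp protocol
sits ≈1 log unit above the up-arm threshold for dLGN units and exactly at
it for retinal units — the in-vivo-only light-adaptation asymmetry is
encoded purely as a preparation-level `adapt_gain` difference, with no
claim about whether the mechanism is retinal or central.

**Rod pathway.** A transient contrast response: a background estimate B
tracks rod flux with time constant `rod_tau_s` (1 s), and the instantaneous
Michelson contrast (F−B)/(F+B) drives firing at `rod_gain` Hz per unit
|contrast| whenever it exceeds `rod_contrast_threshold` (default 0.10, so
4 % controls are sub-threshold and 15 %/30 % supra-threshold). The response
is driven by contrast magnitude — decrements evoke OFF-type firing
increases — which is what makes the flicker calibration scan V-shaped on
both sides of the isoluminant point. Because B is a function of rod flux
alone, rod-silent stimuli produce *exactly* zero rod-pathway modulation:
any detected step response in synthetic data is melanopsin-attributable by
construction, the analogue of the experimental control.

**Unit classes.** Populations mix four classes (default fractions 0.28
steppers, 0.17 irradiance trackers, 0.35 rod-only, 0.20 unresponsive —
calibrated to the reported proportions, documented as calibration rather
than ground truth; allocation is deterministic largest-remainder).
Trackers reuse the melanopsin drive with very slow symmetric filtering
(τ = 300 s) and no threshold adaptation: they follow the slow ramps but
barely register a 30-s step. Preparations transform parameters
idempotently: synaptic blockade zeroes rod gain, halves baseline firing and
slows the melanopsin filter to 7.5 / 38 s; the rodless-coneless retina
slows it to 6 / 50 s and drops per-trial reliability to 0.6. Per-trial
reliability is Bernoulli per step epoch; a non-expressed trial sees the
background continuation instead of the stimulus, keeping the rate
trajectory continuous.

**Spiking.** Inhomogeneous Poisson by thinning of the piecewise-constant
rate (10-ms envelope resolution available; simulations default to 100-ms
rate sampling, much finer than any rate time constant). No refractoriness
in v1. Time-rescaled inter-spike intervals pass a KS test against Exp(1).

## Analysis

* **Detection** — paired two-tailed t-test of baseline-window vs
  step-window mean rates across trials, α = 0.05; responsive additionally
  requires an *increase* (the tested direction). Degenerate zero-variance
  tables return p = 1 (zero mean difference) or p = 0 (consistent non-zero
  difference). On 2000 simulated null units the realised type-I rate sits
  inside the binomial 99 % interval of α; power at the reported effect
  scale (Δ = 1.5 Hz, 5-Hz baseline, 14 trials, 30-s windows) is ≈1.
* **Δ firing rate** — mean step-window rate minus mean baseline-window
  rate; baseline 30 s for steady protocols, 10 s for the ramp protocol
  (the settled hold before each step).
* **Latency** — the trial-averaged rate is estimated in 100-ms bins with a
  3-bin moving average; the threshold line is mean + 1 SD of the baseline
  *time bins* of that averaged trace (the wording "crossed the line"
  describes a rate trace, so the SD is taken over time, not over trials —
  a documented reading of an ambiguous rule). Onset is the first bin
  centre after stimulus onset above the line; offset the first bin centre
  after stimulus offset back *below* it (the return-below reading of an
  ambiguous phrase). Missing crossings are reported as undefined, never
  fabricated; zero baseline SD is flagged and the mean alone used. On
  noiseless constructed rates the estimator is exact to one bin, including
  against closed-form first-order-filter crossing times. Note the rule's
  intrinsic noise sensitivity: a 1-SD line is exceeded by ~16 % of
  baseline bins, so on noisy traces the smoothing window must be wide
  relative to the rise time for crossings to be meaningful. The
  acceptance script therefore computes its population latencies on the
  pooled population PSTH with a 2.5-s boxcar; per-unit latencies at
  1–2-Hz amplitudes and ≲14 repeats are noise-dominated.
* **Repeated-measures ANOVA** — two-way (phase × condition) with subject
  as the blocking factor, via `statsmodels` `AnovaRM`; verified against an
  independent hand-computed sums-of-squares decomposition to 1e−10.
  Post-hoc phase comparisons are paired t-tests Bonferroni-multiplied by
  the number of conditions, capped at 1 — the only multiplicity
  correction used anywhere.
* **Isoluminance scan** — per blue-LED setting, flicker amplitude is the
  absolute mean flash-minus-background rate difference across cycles; the
  null setting is the amplitude minimum provided it is non-significant,
  and a unit significant at every setting is excluded (no isoluminant
  point found).
* **Irradiance tracking** — a unit tracks if the Spearman rank correlation
  between per-segment mean rate and log background flux is significant at
  α = 0.05 with positive least-squares slope. The original report gives no
  criterion for this classification; the rank-correlation rule is this
  package's own.
* **Threshold irradiance** — per ND level, the pooled paired test with
  Bonferroni across levels; the threshold is the dimmest significant
  level, per ramp arm, and the adaptation shift is down-arm minus up-arm
  threshold in log units.
* **Population classes** — step-responsive units are *steppers*; among the
  rest, tracking units are *trackers*. Step response takes precedence,
  mirroring the empirically observed non-overlap of the two types.

## Problem sizes

Simulated experiments use: 200 mixed-class units for end-to-end fraction
recovery (full steady-background protocol, 4 contrasts × 14 repeats; ramp
protocol × 3 repeats); 100 stepper-only units × 6 ramp repeats for the
threshold-shift estimates (the marginal near-threshold levels carry
≈0.13-Hz effects and need ≈600 pooled sweeps to resolve decisively); 30
units × 10 repeats for the retinal latency summaries; 2000/500 simulated
units for detector calibration. These sizes were chosen once as adequate
for the statistics they feed.

## Known limitations

* Rate models are phenomenological; no conductance-level ipRGC biophysics,
  no M1–M6 subtype structure, no suppressed-by-contrast units.
* Poisson spiking without refractoriness; real spike trains are less
  regular at high rates.
* The wedge model uses nominal ND (log-flux span of exactly 4.0 over
  ND4–ND0). The printed endpoint irradiances of the original apparatus
  span 3.80 log units — a calibration detail of that hardware the fixture
  does not reproduce; reported log values there also appear rounded to
  1 decimal.
* Passing tests on synthetic data show the pipeline recovers structure the
  generator planted under its assumptions (exact rod silence, Poisson
  noise, stationary baselines); they do not certify performance on real
  recordings with drift, sorting errors or correlated noise.
* The "5.7-fold = 71 %" pairing quoted for the original stimuli is
  internally inconsistent by rounding (5.7-fold ⇒ 70.1 %; 71 % ⇒
  5.90-fold); the solver reports unrounded values and makes no attempt to
  reconcile them.
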