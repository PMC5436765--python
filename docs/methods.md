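# Methods

## Model

The rat HPA axis is represented as a stoichiometric network of 11 circulating
species and 25 lumped reactions under the law of mass action. The reactions
are not elementary chemistry: each summarizes a physiological pathway
(hypothalamic CRH release, ACTH-driven adrenal steroidogenesis from
cholesterol through pregnenolone/progesterone to corticosterone, receptor-
mediated feedback, first-order elimination). Receptor (GR/MR) levels are
folded into the rate constants and are not state variables. Products of the
pure-removal steps R16–R25 are unmodeled sinks. Concentrations are molar and
time is in minutes, matching the units in which the rate constants are
expressed; no internal rescaling is applied anywhere.

Two structural choices deserve comment.

* **Catalytic CRH→ACTH (R4).** The stimulated-release step is implemented as
  CRH → CRH + ACTH: CRH acts as a trigger and is removed only by the
  corticosterone feedback (R16) and first-order clearance (R19). The
  alternative literal reading, in which R4 consumes CRH, makes the
  frozen-forcing fixed point a stable focus (leading eigenvalues
  −0.030 ± 0.027i min⁻¹): the system relaxes to a smooth circadian-only
  trajectory with no ultradian rhythm, which contradicts the defining
  behaviour the model exists to produce. With the catalytic reading the
  fixed point is an unstable focus (+0.030 ± 0.074i min⁻¹) and the model
  oscillates with a ~57 min period, 24 h entrainment, and a control daily
  mean of ~82 ng/mL corticosterone — all in the physiological range. R5
  (ACTH + CHOL → PNN) is kept literal; making it catalytic as well
  destroys the oscillation again.
* **Feedback stoichiometry as written.** R15 (ALDO + 2 CTS → CTS) is a
  third-order step overall even though its biological role is quadratic
  autoinhibition of corticosterone; it is implemented with that exact
  stoichiometry.

The right-hand side and its analytic Jacobian are hand-coded closed-form
balance equations; a structural test verifies them against the generic
stoichiometry-matrix × rate-vector product on 1000 random states to 1e-12
relative.

## Circadian forcing

D(t) (README) multiplies the CRH production constant k2. t = 0 is 00:00 of
day 1, so the phase parameter 840 min places the zero of both trigonometric
terms at 14:00 and the maximum of the drive around 21:55, giving the
nocturnal corticosterone rise expected for rats. With default parameters D
is strictly positive (minimum ≈ 0.0656 near 12:27) and exactly 1440-min
periodic. The rectified-sine term makes the rise and fall asymmetric.

## Numerical integration

The system is stiff, so only implicit/stiff schemes are allowed. Presets:

* **strict** (default): atol 3e-20, rtol 1e-14, LSODA (Gear-family
  multistep). SciPy refuses relative tolerances below 100·eps ≈ 2.22e-14;
  the configured value is stored as given and clamped to that floor at solve
  time.
* **fast**: atol 1e-9, rtol 3e-6, Radau. At relaxed tolerances the
  fully-implicit Radau scheme tracks the oscillation phase far better than
  the multistep methods (day-2–5 daily means within 0.05% of the strict
  reference, versus ~2% for LSODA at the same tolerances), which is why the
  fast preset pairs the relaxed tolerances with Radau rather than LSODA.

Kindling pulses use stop-and-restart semantics: integration halts at the
event time, the CRH concentration is incremented, all other species keep
their attained values, and integration resumes. The default 50-min sequence
holds 75 pulses (first pulse at the start, every 40 s, none at or after
start + 50 min); the 72 h protocol uses the same mechanism with 6,480
restarts. Output is dense (≤1 min spacing plus all event times); the state
stored at an event time is the pre-pulse state, with pre/post values kept in
per-pulse records so pulse bookkeeping is exactly testable. Values below
1e-30 in magnitude are floored to zero. All scenarios start at t = 0 from
the shared standard initial condition; day 1 is treated as transient and
excluded from every analysis.

## Oscillation metrics

Ultradian peaks are detected on the series minus its 6 h moving median
(detrending removes the circadian envelope) with a prominence threshold of
5% of the detrended window's interquartile range — both exposed as
arguments. The defaults resolve a synthetic 80-min sinusoid on a 24 h
baseline and the control scenario alike, and the relative threshold makes
detection invariant to uniform rescaling. Reported metrics: median
inter-peak interval; peaks per 24 h; median (peak − following trough) read
from the raw series; the raw (highest peak, lowest trough) of the
largest-amplitude pair; per-day means; and a circadian modulation index
(max − min)/(max + min) of the 6 h rolling-max envelope, which collapses
toward zero as circadian structure is lost. Fewer than two detected peaks
flags the metrics absent (None), never zero. The circadian period is the
lag of the autocorrelation maximum searched over 18–30 h and requires ≥4
analysed days.

Unit/dosing helpers: ng/mL = M × molar mass × 1e6; corticosterone molar
mass defaults to 346.46 g/mol and CRH to 4758 g/mol (41-residue peptide),
both arguments. The stimulation-test calculator accepts either a total
blood volume with body mass, or a per-kg blood volume (mass cancels).

## Synthetic sampling

The generator emulates the in-vivo protocol: 31 samples of 50 µL over ~24 h
(total draw 1.55 mL) in two interval schedules anchored to the 21:12–22:02
kindling window — variant A: 23 hourly samples, six 10-min samples through
kindling, two 30-min samples after; variant B: one sample 50 min before
kindling, six 10-min samples through it, 24 hourly samples after. Assay
error is multiplicative log-normal with median 1 and CV 4.1% (the
inter-assay CV of the corticosterone ELISA); log-normality is a modeling
choice that guarantees positive "assay" values and median-unbiasedness.
Samples are lost independently with a configurable probability, keeping
their schedule slot (value NaN). Cohorts draw per-animal seeds from one
master seed, so regeneration is bit-identical.

What the generator does **not** emulate: systematic inter-animal
physiological variability (off by default; can be approximated upstream by
jittering the k2 multiplier between input trajectories), hypovolemic stress
feedback from the draws, assay calibration drift, and detection limits.
Passing tests therefore demonstrate correctness of the pipeline under the
stated noise model, not robustness to real-animal heterogeneity.

## Calibration

Both fits minimize summed squared residuals between noiseless model
predictions at the sample times and the measured values, in ng/mL (the assay
scale, shared with the noise model). Grid search is the reference method;
the stress-multiplier fit optionally refines the grid argmin with a bounded
scalar minimization, reporting both.

The pointwise objective is **phase-sensitive**: away from the generating
parameter the ultradian oscillation de-phases from the data, so the SSR
landscape is rugged with one deep, narrow basin at the truth. Consequences,
measured on this model:

* the stress-multiplier basin has half-width ≈ 0.005, so the default grid
  spans 1.0–1.3 at 0.005 spacing (61 points); coarser grids can lock onto
  spurious phase coincidences far from the generator;
* the pulse-intensity objective is not monotone along a log grid — but the
  truth basin sits many orders of magnitude (>10⁶×) below every other
  candidate, so the argmin is unambiguous when the grid can express the
  generating value. The corticosterone response during kindling is a fast
  adapting spike (~10⁴ ng/mL at +10 min, back below baseline by +50 min
  while pulses continue) whose flank values are so intensity-sensitive that
  a grid *not* containing the generating value is dominated by quantization
  error: every undershooting candidate misses the +10 min sample by a
  similar amount and the argmin collapses to the smallest candidate.
  Calibration grids should therefore include the nominal intensity; the
  recovery experiments use a 9-point log grid over two decades centred so
  the nominal 5e-8 M is a grid point.

Candidate simulations share the pre-kindling segment (integrated once and
branched), which also makes the noiseless self-consistency exact: data
generated by the model at a grid candidate yields SSR = 0 at that candidate.

The group comparison is a standard pooled one-way ANOVA (all present
samples per group), with between/within degrees of freedom reported.

## Problem sizes and runtimes

Default study sizes: 5 simulated days for control/sham (strict preset,
seconds per run), 3 days for the 50-min kindling scenario, and 5 days with
6,480 pulse restarts for each 72 h kindling intensity (fast preset, tens of
seconds per run). The parameter-recovery experiment uses 20 noise
realizations of 4 animals over a fixed 9-candidate prediction set, and the
ANOVA null calibration uses 1,000 three-group cohorts of 18 i.i.d. values.

## Known limitations

* The kindled corticosterone spike (~10⁴ ng/mL ≈ 30 µM) exceeds
  physiological levels by two orders of magnitude; the model's value lies in
  its rhythm structure and orderings, not in absolute kindled amplitudes.
* Ultradian frequency under sustained 72 h kindling is not strictly monotone
  in pulse intensity here: ~26.3 peaks/day at 2e-8 M, ~24.7 at 2e-7 M, ~33.7
  at 1e-6 M (days 3–5; stable under tighter tolerances and across prominence
  thresholds). Amplitude is strictly monotone and circadian modulation at
  1e-6 M falls well below the sham level (0.67 vs 0.875).
* The sham scenario's autocorrelation-based circadian period reads 24.5 h
  (control: exactly 24 h); the estimator's resolution is set by the lag grid
  and the interaction of ultradian and circadian peaks in the
  autocorrelation.
* No delay terms, no receptor states, no stochastic (discrete-molecule)
  kinetics, no spatial structure; the constants are taken as given, not
  re-derived.
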