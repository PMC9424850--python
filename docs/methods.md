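# Methods

## Session model and cycle structure

A session is one participant tapping four touch screens in fixed
counterclockwise order for 400 cycles at one worktable height. Cycle i
spans the i-th TS1 tap to the (i+1)-th; the four stages ST1..ST4 are the
inter-screen intervals inside it. All per-cycle and per-window values
are pooled into 10 bins of 40 cycles (an incomplete final bin is kept
but flagged, or dropped by configuration). Tap logs are validated
strictly: timestamps must increase and screens must advance cyclically;
a log with a dropped event is a schema error rather than a partially
recovered session, because a missing tap makes the cycle and stage
structure ambiguous.

## EMG chain

* **Conditioning**: 4th-order Butterworth band-pass, 10–950 Hz, applied
  forward–backward (zero phase) per channel. At fs = 1926 Hz the upper
  edge sits just below the 963 Hz Nyquist frequency; an edge at or
  above Nyquist is rejected.
* **Windows**: 0.125 s rectangular windows with 50% overlap (0.0625 s
  step) for both RMS and MF; window length is truncated to an integer
  sample count (240 samples at 1926 Hz, 120-sample stride).
* **%MVC**: the MVC reference per channel is the maximum of the moving
  RMS over the MVC trial. Windows centered within 0.25 s of either
  record edge are excluded from that maximum: the zero-phase filter's
  startup transient otherwise inflates an extreme-value statistic (the
  mean-based task windows are insensitive to this).
* **Median frequency**: per window, a Hamming-tapered periodogram; MF is
  where cumulative power reaches half the total. Bin k's power is
  treated as occupying [f_k − Δf/2, f_k + Δf/2] and the crossing is
  interpolated linearly inside the crossing bin. Interpolating on bin
  centers instead would bias MF low by about half a bin (≈4 Hz here) on
  any broadband spectrum. All-zero windows yield NaN (missing), never 0.
* **Per-bin MF** is the mean of the window MFs assigned to the bin's
  cycles (windows assigned by center time). Pooling spectra before
  taking the median would be the alternative; mean-of-windows matches
  the per-window definition and is what the generator contract targets.
* **CCI** uses the anterior deltoid as agonist and posterior as
  antagonist; since the numerator is the pointwise minimum, the value is
  invariant to that assignment. Trapezoidal integration over window
  centers inside the interval; a vanishing denominator gives NaN with a
  warning. For two nonnegative envelopes CCI ∈ [0, 50], with 50 iff the
  envelopes coincide on the interval.

## Kinematics

Cycles are linearly resampled to 100 phase points (endpoints included);
each stage separately to 25 points so stage-level variability is
comparable across stages of different durations. KV uses the sample SD
(n−1 denominator) across a bin's cycles at each phase point, averaged
over phase, per channel; a sensor's KV is the Euclidean norm of its
three axis values. KV is translation-invariant and scales linearly with
amplitude; a bin with fewer than two cycles is missing.

## Local dynamic stability

The state space is the three dominant principal-component score series
of the nine concatenated (time-normalized) acceleration channels —
columns centered, not variance-scaled, PCA fitted per height session.
No additional delay embedding is applied: the multichannel projection
already supplies three coordinates. Variance fractions are reported
against total variance.

Divergence is Rosenstein-style: each reference point is paired with its
nearest Euclidean neighbor at least one full cycle away (Theiler window
= 100 samples, excluding trivially phase-adjacent neighbors in periodic
data), and y(k) is the mean log distance after propagating both ends k
samples, k = 0..50. λ at horizon h is the least-squares slope of y(k)
over k ∈ [0, h] (no transient skip), for h = 5, 10, 25, 50 samples; one
sample is 1% of a cycle, so per-cycle exponents are 100× these.

Within the per-bin pipeline, reference and candidate points are
restricted to those that can be propagated the full 50 samples without
crossing a cycle boundary, and that reference set is held fixed across
k. Two reasons. First, cycle-to-cycle perturbations in cyclic movement
(and, exactly, in the generator) re-initialize at cycle starts, so a
pair propagated across a boundary measures re-initialization, not
divergence. Second, a reference set that shrinks as k grows changes the
phase composition of the mean and biases the slope of y(k) downward by
up to half when perturbation magnitude grows within the cycle; the
fixed set makes the slope estimate exact on planted-exponent data. The
generic `divergence_curve` without segment boundaries (all points as
references, per-k record-end exclusion) remains available and is what
the brute-force oracle tests exercise.

On a standard 3-D chaotic flow the same estimator, fitted on the
exponential plateau after the neighbor-convergence transient, agrees
with a Benettin-style tangent-propagation oracle within a few percent
(test suite, 15% tolerance).

## Task performance

AS = 100 · (r − d)/r with d the tap-to-center distance in mm
(pixel pitch 0.153 mm/px) and r the circle radius. The hardware
documentation gives the displayed circle as 33.66 mm in one place and
16.83 mm (110 px) in another — exactly a factor of two, so one of them
is the radius; this package takes 110 px as the *diameter* (r = 55 px =
8.415 mm), and the choice is configurable. AS is not clamped: taps
outside the circle score negative.

TD is deliberately a *precision* measure, distinct from AS's *accuracy*:
the mean distance of a bin's taps from their own centroid. TD is never
given a formula in the hardware-study literature this mirrors; the
centroid-referenced mean distance is the central interpretive decision
here, and a center-referenced RMS variant is available behind
`td_mode="center_sd"`. For isotropic bivariate normal scatter with SD σ
per axis, TD → σ√(π/2).

Task time is the difference of successive TS1 timestamps, averaged per
bin.

## Inference

Bin values are normalized per participant to ratios of the first LOW
bin (so height effects survive); MF indices are normalized to the first
bin of their own height, since MF baselines are not comparable between
days. Height comparison: two-sided paired t-test pooling participant ×
bin pairs (18 × 10 in the full design). This pooled pairing matches the
group sizes of the original protocol but treats within-participant bins
as independent pairs, which is anticonservative; it is retained
deliberately and noted here. Time effects: bins pooled into five 2-bin
periods (participant-level period means), one-way repeated-measures
ANOVA per height (classical subject × period decomposition, no
sphericity correction — a Greenhouse–Geisser-style correction was
considered out of scope), and only if the ANOVA rejects are the four
paired follow-ups (P2..P5 vs P1) run at the Bonferroni level
0.05/4 = 0.0125, which keeps the family-wise error of the whole
procedure at or below 0.05 (verified by simulation). Identical paired
vectors return t = 0, p = 1 rather than NaN. Subjects with missing
periods are dropped from the ANOVA (complete-case) and logged.

## Synthetic data generator

The generator is first-class: every downstream index has a planted
value it must recover.

* **EMG**: white noise shaped in 0.5 s Hann overlap-added segments by a
  flat pass-band centered on the target MF (default half-width 90 Hz,
  shrunk symmetrically near the 10 Hz floor or the Nyquist ceiling) —
  the MF of a flat band is analytically its midpoint. Each 120-sample
  chunk is then rescaled so the windowed RMS matches the target
  exactly on the analysis grid. One guard segment is synthesized and
  trimmed at each end so the OLA taper never reaches the record.
  Recovery: windowed MF within ±5% and RMS within ±3% of the profiles,
  away from edges. The MVC trial is a separate 5 s constant-amplitude
  record at the configured MVC level, so task %MVC equals the
  configured activation fraction.
* **Acceleration**: 9 channels = (9×3 mixing matrix) · latent(t) +
  smooth noise. The latent is a cyclic template — an ellipse-like
  closed curve (amplitudes 3.6/3.0/1.5 m/s², realistic for arm
  acceleration) chosen because it has no state-space
  self-intersections: distinct phases keep a guaranteed distance, so
  nearest neighbors are phase-aligned and the planted exponent is
  measurable. A template with near self-crossings mis-pairs up to a
  quarter of the neighbors and inflates short-horizon slopes severalfold.
  The perturbation is re-seeded per cycle (random unit direction,
  amplitude 0.01 m/s² at cycle start) and its log magnitude grows at
  exactly `divergence_gamma` per phase sample, so the planted λ is
  exact by construction; a chaotic-flow fixture provides the
  independent cross-check in tests. The additive channel noise is
  low-passed (10 Hz) white noise rescaled to an exact per-sample SD:
  smoothness makes its pointwise SD survive the linear resampling onto
  the phase grid, which would shrink interpolated iid noise by up to
  √(2/3) and destroy KV recovery.
* **Taps**: bivariate normal (σ, bias) around each circle center in mm,
  converted to pixels (kept as floats; quantizing to the 0.153 mm pixel
  grid would perturb σ recovery by <0.1%). TS1 times follow a linear
  duration trend; TS2..TS4 sit at quarter points.
* **Accelerometer rate**: not fixed by the hardware description;
  default 100 Hz, configurable.

Defaults are the two-height study conditions: HIGH plants steeper MF
decline (80→70 vs 80→77 Hz anterior), higher activation (14 vs 10 %MVC
anterior, with relatively stronger antagonist activity, i.e. higher
CCI), larger tap scatter (1.7 vs 1.2 mm), higher movement variability
(0.22 vs 0.15 m/s²) and slightly faster cycles (≈1.95–2.05 vs
2.0–2.2 s). Two dedicated validation designs isolate parameters whose
recovery would otherwise interfere: the λ-recovery design makes channel
noise negligible (2×10⁻⁴ m/s²) so neighbor distances are
perturbation-dominated over the whole fitted horizon, and the
KV-recovery design switches the perturbation off. These choices follow
from the noise-floor analysis above, not from tuning against observed
outcomes.

What the generator does **not** emulate: realistic muscle or limb
dynamics (EMG is shaped noise, not motor-unit activity; acceleration is
a fixed template, not biomechanics), electrode or soft-tissue artifacts,
mains hum (a notch hook exists but defaults off), between-participant
baseline differences (cohort participants differ only by random
realization), and any speed–accuracy coupling between the planted tap
scatter and cycle durations. Passing recovery tests therefore shows the
*estimators* are correct and calibrated, not that real recordings meet
the generator's assumptions.

## Problem sizes and numerical notes

Recovery experiments run at the full 400-cycle session size; statistical
calibration uses 1000 null replicates at the 18-participant design; the
cohort driver simulates 8 participants at 200 cycles as its own
reporting choice. Window counts are exact-integer: 240-sample windows,
120-sample strides. The divergence search excludes zero distances from
log means (counted and logged). PCA rank below 3 and rank-deficient
mixing matrices are rejected with guidance. Session CSVs are written
with 17 significant digits and read with round-trip float parsing, so
write→read is bit-exact.

## Known limitations

* The pooled participant × bin pairing of the height t-test is
  anticonservative (see Inference); a participant-aggregated variant is
  a one-line change on the ratio table.
* λ values from the cycle-confined estimator are not directly
  comparable to implementations that propagate pairs across cycle
  boundaries; on real (non-re-initializing) data the difference is
  small but nonzero.
* Stage-level KV resamples each stage to 25 points; raw-duration stage
  slices would weight stages by duration instead.
* The generator's %MVC recovery carries a ≈1% downward bias from
  band-pass attenuation of the synthesis band's edges; directional and
  ratio-based comparisons are unaffected.
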