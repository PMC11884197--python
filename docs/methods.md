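# Methods

This note documents the models, numerical choices and limitations behind
`subkin`: the submovement detectors, the error measures, the statistics
layer, and — in most detail — the synthetic cohort generator, because its
design determines what passing tests do and do not demonstrate.

## Signal model and detectors

The data are 1-D stylus positions x(t) at a nominal 100 Hz, tracking a
sinusoidal target x_stim(t) = x_c + (A/2)·sin(2πf(t − t₀) + φ) presented in
constant-frequency segments of 18–22 s after a 5 s stationary lead-in.
Frequencies span 0.25–0.5625 Hz (6 levels) and end-to-end amplitudes
6.3–33.2 cm.

**Filtering.** Two-way (forward–backward) Butterworth low-pass, design
order 4, applied once to position. "Order 4" names the single-pass design;
the zero-phase double pass squares the magnitude response, so the effective
gain is 1/(1 + (tan(πf/fs)/tan(πf_c/fs))⁸) — the tan terms are the bilinear
design's frequency prewarping, which matters in the stopband (gain 1/290
rather than the analog 1/257 at f/f_c = 2, fs = 100 Hz). The submovement
chain uses f_c = 4 Hz so that 4–6 Hz tremor is not counted as submovements;
the error chain uses 10 Hz; both are config keys (`cutoff_submovements`,
`cutoff_errors`), so the 10 Hz re-analysis of the submovement measures is a
flag, not a code change.

**Derivatives.** Central differences in the interior, one-sided at the
endpoints, applied to the already-filtered position; no re-filtering
between stages. Speed is the rectified velocity |dx/dt|; "acceleration" and
"jerk" in this package always mean derivatives of speed, which is what the
sign rules below require. Speed is invariant under x → −x, so all counts
are mirror-invariant.

**Type 2 detection.** Zero crossings of acceleration from + to − (speed
peaks), with linear interpolation between flanking samples; a sample
exactly at 0 attaches to the preceding sign run. Peaks within ±50 ms
(two-sided; the convention is configurable via `window_ms`) of an analytic
stimulus speed-peak time are flagged excluded and do not enter rates.
Stimulus speed peaks are enumerated analytically at intervals 1/(2f) on the
half-open segment [t_start, t_end).

**Type 3 detection.** Jerk zero crossings from − to + while acceleration
> 0, or + to − while acceleration < 0, with acceleration evaluated by
interpolation at the crossing time; |a| < 10⁻⁹ cm/s² disqualifies the
degenerate flat case. No stimulus-peak exclusion is applied to type 3. An
isolated minimum-jerk speed bell produces zero type 3 events — both its
jerk crossings carry the disqualifying acceleration sign — whereas a
"shoulder" (two partially merged bells) produces exactly one; the unit
tests pin both facts.

**Edge handling.** `filtfilt`-style odd reflection padding suppresses most
filter transients; in addition, events in the first and last 0.5 s of each
segment (`edge_exclusion_s`) are dropped, and rates divide by the analysed
duration (segment minus the guard zones). Strokes are counted analytically
as 2·f·duration: in a tracking task the stimulus defines the stroke
structure, so empirical reversal counting would only add noise.

**Type 1 submovements** (overshoot corrections) are deliberately not
computed; overshoot is not a feature of continuous tracking.

## Error measures

Registration minimises the mean squared difference between the participant
trace advanced by τ samples and the stimulus, over integer τ ∈ [0,
max_lag·fs] (default 1 s; tracking a visible target is reactive, so
negative lags are off by default and available behind
`allow_negative_lag`, which reports |τ|). Ties break toward the smaller
lag; there is no sub-sample refinement. The minimiser is the mean timing
error dT ≥ 0.

dX is computed on the registered pair against the analytic stimulus, with
x_c taken from the segment definition, never estimated from data. Samples
with |x₁ + x₂ − 2x_c| < 10 px (converted to cm via `pixels_per_cm`,
default 42.9 for the 27-inch 2560×1440 display geometry) are dropped and
counted. For a pure gain error x₁ − x_c = (1+e)(x₂ − x_c) the measure has
the closed form dX = 2e/(2+e), which the tests use as an oracle; dX is
invariant under joint rescaling of both traces about x_c, which is the
amplitude normalisation the denominator is for.

## Statistics

The `OutcomeModel` front end aggregates segment-level metrics to
participant × frequency cells (warning about, and excluding from the
ANOVA, participants with incomplete designs), then runs:

- a mixed-design ANOVA (between: group, within: frequency) via pingouin;
  when Mauchly's test rejects sphericity at p < 0.05, the within and
  interaction effects use Greenhouse–Geisser-corrected degrees of freedom
  (pingouin reports ε and the corrected p for the within effect; the
  interaction's corrected p is computed from the same ε). The tests check
  the F statistics against an independently hand-coded sums-of-squares
  decomposition for the balanced design.
- Holm-corrected pairwise two-sample t-tests on participant means averaged
  over frequency (the main-effect level), with pooled-SD Cohen's d.
- per-participant OLS slopes of each measure on frequency, a two-sided
  one-sample t-test of the slopes against zero, and d = mean/SD of slopes.
- `ttest_power_n`: smallest integer per-group n reaching a target power
  for a two-sided two-sample t-test, with effect size |Δμ| over the pooled
  SD √((s₁²+s₂²)/2) and exact noncentral-t power (normal fallback where
  scipy's noncentral t loses precision). Treating reported "±" dispersions
  as SDs reproduces the classic planning result used for this design
  (66.0 ± 2.9 vs 69.5 ± 4.2, power 0.95 → 29/group).
- p-values are labelled significant below 0.05 and "trend" in (0.05, 0.1),
  matching the field's reporting convention.

## Synthetic cohort generator

The generator exists so that every stage — detection, registration, the
statistical battery — can be validated against known ground truth at the
study's own conditions: three groups (PwP / OC / YC) of 30 participants,
11 one-minute trials each, three 18–22 s constant-frequency segments per
trial after a 5 s lead-in, six frequencies crossed with amplitudes
6.3–33.2 cm. Segment durations are quantised to whole half-periods so the
target stays position-continuous across frequency changes.

A simulated tracker is open loop: response = centre + gain·(stimulus(t −
lag) − centre), plus three structured disturbances. There is no
feedback-control model; corrections are injected, not emergent.

**Reaction lag** is drawn per participant from the group's dT distribution
(means 0.183 / 0.147 / 0.102 s for PwP / OC / YC, SD 0.05 s). Because the
lag exceeds the 50 ms exclusion window, the tracker's own lagged speed
peaks register as type 2 events at 2f per second — a structural floor the
design accounts for.

**Gain error** supplies dX. Since the injected disturbances themselves
produce position error (a measured, frequency-rising excess of ~0.12–0.34),
each participant's gain at each frequency is set so that gain error plus
excess meets that participant's dX target (group means 0.389 / 0.265 /
0.181 with per-Hz slopes 1.16 / 0.75 / 0.53 and the corresponding
between-participant spreads). Where the target sits below the structural
excess — the younger controls at mid frequencies — the gain bottoms out
and realised dX sits on the floor, compressing the YC–OC contrast there.

**Corrective pulses** are two-phase velocity bells: a fast sin² attack
(0.18 s) and a slow cos² release (0.45 s), time-reversed when placed on an
accelerating quarter-cycle (under the zero-phase filter the reversed pulse
on a mirror-image baseline behaves identically). The asymmetry is the
point: a symmetric bell bends the speed profile on entry *and* exit and is
detected twice, while the gentle release stays below the baseline jerk and
leaves exactly one event. Strong pulses (attack acceleration 1.7× the
local baseline) carve a distinct speed peak — one type 2 event; weak
"shoulder" pulses (amplitudes from a measured minimum-detectability table
over frequency × phase, margin 1.35, capped below the acceleration-flip
limit) bend a single qualifying inflection — one type 3 event. Pulses are
placed in calibrated phase zones away from stimulus-peak exclusion
windows, response speed peaks and reversals, with ≥ 0.2 s spacing; each
pulse's displacement is taken back by a sub-threshold smooth return
(1.8 s), so traces stay near the target without counterfeit events. In the
noise-free regime the type 2 detector recovers injected pulse counts to
within ±10% across the default grid (a pinned test).

**Motor wobble** is the main type 3 source: band-limited (1.5–3.5 Hz,
inside the analysis band) Gaussian noise scaled by each segment's movement
amplitude (signal-dependent motor noise), with SD 0.018 cm at the
reference amplitude and a participant spread of 0.011. Its jerk is roughly
constant while the baseline jerk grows as V·ω² ∝ f²·A, so wobble-induced
inflections are frequent in slow strokes and rare in fast ones — this
single mechanism produces the frequency-declining type 3 (and pooled)
rate, the package's structural rendition of "slow movements cannot be made
smooth". The PwP type 3 offset (+0.31 events/s on the detected scale)
rides on the wobble amplitude (0.033 cm per unit rate, a calibrated
sensitivity) plus a small shoulder-pulse top-up at the two highest
frequencies where the wobble sensitivity flattens; sensor noise is white
Gaussian, 0.005 cm. An optional fixed-frequency tremor sinusoid (default
6 Hz, above the 4 Hz cutoff) models parkinsonian tremor; at the amplitudes
that survive screening it leaves 4 Hz-cutoff counts untouched while
visibly contaminating a 10 Hz analysis, which is the rationale for the low
cutoff.

**Calibration.** All transfer constants — pulse placement zones, the
minimum-detectability table, the wobble sensitivity, the dX excess — were
measured by simulating probe signals through the package's own filtering
and detection chain at the default operating point and are frozen in the
module. They are part of the generator's definition, not tuning knobs.

**What the synthetic cohorts do not emulate.** Absolute type 3 levels run
lower than in real cohorts (~0.9 / 0.65 / 0.75 events/s for PwP / OC / YC
instead of ~1.7 / 1.4 / 1.4): the event economy of the slowest strokes
saturates, and pushing the base level higher would destroy the group
offset's transmission, which the validation cares more about. Group
contrasts, their ordering, the frequency decline, dT levels and dX
ordering are faithful. Real data additionally contain closed-loop
error-dependent corrections, drifting lags, within-trial fatigue and
movement-extent undershoot, none of which are modelled; consequently,
passing the parameter-recovery tests shows the pipeline recovers known
structure through the full measurement chain, not that the generator is a
behavioural model of tracking.

## Problem sizes in the validation suite

The test suite exercises reduced-scale cohorts chosen to keep the full
validation cheap while preserving the per-cell design: replicate cohorts
use 2 trials of three 12 s segments per participant (one segment per
frequency per trial), n = 30/group for recovery checks (50 replicates) and
n = 10/group for the null-calibration study (200 replicates). The
acceptance script runs the full default design (11 trials, 18–22 s
segments, n = 30/group). Type-I error of the mixed ANOVA's group effect on
null cohorts is checked against the nominal 5% ± 2 points.

## Known limitations

- The registration objective (integer-lag MSE) is an assumption; the
  deposited dataset's original analysis cites an external registration
  procedure whose exact objective is not restated there. The adapter
  (`Dialect`, `load_figshare_dataset`) must be configured against the
  actual deposit layout before recorded data can be reproduced.
- Whether filtering preceded differentiation in the original analysis is
  not stated; this implementation filters position once, then
  differentiates.
- The 50 ms stimulus-peak exclusion is interpreted two-sided.
- Events are detected on a 10 ms grid with linear interpolation; no
  sub-sample refinement of event times beyond interpolation is attempted.
- No smoothing-spline or Savitzky–Golay derivative alternatives; no
  decomposition into overlapping minimum-jerk primitives (detection is
  purely zero-crossing-based); no Bayesian ANOVA.
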