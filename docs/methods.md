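# Methods

This note documents the models and procedures implemented in `gazeflow`, the
parameters that matter, and the choices made where the design was genuinely
open.

## Gaze-event classification

Gaze is a stream of unit direction vectors in the headset frame, nominally
90 Hz. Angular speed over each inter-sample interval is the great-circle
angle between the bounding directions divided by the elapsed time; the 3D
formulation (rather than 2D screen coordinates) is deliberate, since a
headset tracker has no privileged screen plane and the same computation must
serve both viewing modes.

Classification is adaptive velocity thresholding (I-VT): the threshold is
`threshold_multiplier` (default 5) times the **median** trial speed, so it
adapts to per-trial noise without any absolute calibration. Maximal runs of
intervals above the threshold become saccades when the run lasts at most
`saccade_max_ms` (50 ms); runs at or below it become fixations when they
last more than `fixation_min_ms` (100 ms); all other runs are left
unclassified rather than forced into either class. Decisions that the
definition leaves open, fixed here as contracts:

- **Median scope.** The median is computed per trial. Per-trial adaptation
  tracks per-video noise and is the most local defensible choice; the scope
  could equally be per participant, and the function accepts any velocity
  series, so callers can pool as they wish.
- **Ties.** A speed exactly at the threshold counts as *below* (fixation
  side). Arbitrary but fixed and tested.
- **Boundary runs.** Runs touching the trial start/end are classified
  normally. Trials are ~3.6 s; discarding boundary fixations would bias
  counts low by a substantial fraction.
- **Gaps.** Invalid runs (dropouts, blinks, unnormalizable samples) longer
  than `gap_bridge_ms` (75 ms, a conventional blink floor) split the
  segmentation and are reported as gaps, so events plus gaps tile the trial.
  Shorter gaps are bridged assuming constant angular velocity between the
  flanking valid samples. Invalid samples are never silently dropped on
  read, precisely so this stage can see them.
- **No smoothing** is applied by default; an optional 3-sample median filter
  on speed exists behind a switch.

Per-trial metrics: fixation and saccade counts are normalized by
`ref_duration_ms / duration_ms` with `ref_duration_ms = 3600` (the mean
stimulus duration), putting counts from videos of different lengths on one
scale; mean fixation duration; and search rate = fixation count ÷ summed
fixation duration in ms⁻¹, exactly as defined — no attempt is made to match
any particular printed order of magnitude for this quantity. With no
fixations, duration-based metrics are missing (NaN) and are dropped
listwise by the models.

## Head excursion

Orientation quaternions decompose intrinsically yaw(z, vertical) →
pitch(y, lateral) → roll(x, forward); angles are unwrapped per axis.
The capture SDK's native convention varies by vendor, so the convention is
a documented package contract, pinned by a test against an independent
rotation-matrix decomposition. Excursion per axis is the cumulative absolute
angular path, duration-normalized like the counts. Path length (rather than
net range or a count of discrete rotations) is the reading consistent with
tens-of-degrees magnitudes over ~3.6 s trials and with the scanning
literature; a range mode (max − min) is available behind `mode="range"`.
Near the pitch gimbal (|pitch| > 89°) a warning is emitted and values are
still returned. No low-pass filtering is applied; an optional
`min_step_deg` floor (default 0 = off) can suppress tremor-scale steps.

## Workload and heart rate

The ten SIM-TLX items are validated (exactly ten items, each in [0, 20])
and analyzed item-wise; no composite index or pairwise weighting is
computed. Scores are carried at 0.1 resolution. Mean heart rate per
participant × condition is range-checked (30–220 bpm) and treated as a
control variable with the same model structure.

## Mixed-model inference

Each response is fit by REML (statsmodels `MixedLM`) with 0/1
treatment-coded fixed effects for condition, sex and their interaction, and
a participant random intercept — intercept-only, with no stimulus random
effect, matching the stated design. Gaze/head metrics are modeled at trial
grain (the design presents 24 stimuli per participant per condition);
SIM-TLX items and heart rate exist once per participant × condition and are
modeled at participant grain.

Numerical choices: the response is standardized by its SD before
optimization (responses range over six orders of magnitude across metrics;
ms⁻¹-scale search rates otherwise produce singular working matrices) and
estimates are rescaled afterwards; the optimizer cascades
lbfgs → powell → cg → nm, since the gradient-based optimizer can step into
a singular covariance on heavy-tailed trial metrics; a random-intercept
variance estimated at the boundary is reported as a singular-fit warning
with the variance floored at 0.

Denominator degrees of freedom use the between-within (inner-outer) rule:
terms varying within participants are tested on N − G − q_within df, purely
between-participant terms on G − q_between − 1. This closed-form
approximation reproduces the paired t-test exactly in the balanced
one-observation-per-cell case (a tested invariant) and is asymptotically
equivalent to Satterthwaite-type approximations at this design's size,
without requiring derivatives of the variance-parameter covariance.

Effect sizes are standardized betas (β ÷ response SD with 0/1 predictors),
labeled small/medium/large around the 0.2/0.5/0.8 anchors with boundaries
at the midpoints 0.35/0.65. Post-hoc pairwise comparisons of estimated
marginal means (equally weighted over the other factors' levels) use the
studentized-range distribution; with a two-level factor the single contrast
reduces to the coefficient test. Model families are reported item-wise at
α = 0.05; a Holm-adjusted column is included in the report for transparency
but is not the headline inference.

## Synthetic data generator

The generator emulates the study design: 32 participants (16 per sex,
condition order counterbalanced), 24 trials per condition (six per punch
type), 90 Hz sampling, trial durations lognormal around 3600 ms (SD 400 ms,
a chosen plausible spread). Channel defaults are the per-condition group
means/SDs of the reference conditions: fixation duration 457.5 ± 198.8 ms
(2D) / 365.8 ± 170.1 ms (VR); roll 39.9 ± 18.8 / 55.7 ± 22.3°; pitch
41.8 ± 16.6 / 71.2 ± 35.1°; presence 7.8 ± 5.4 / 15.1 ± 3.4. Yaw is
generated condition-invariant (45° both conditions), as are the nine
non-presence questionnaire items (mid-scale values chosen once); heart-rate
means are sex- and condition-specific (96.6/95.1 F, 90.5/90.4 M, ~11.5 bpm
marginal SD).

Each marginal SD is split into a participant random intercept (between SD:
fixation 80 ms; roll/pitch/yaw 9/10/8.5°; presence 2.0; items 1.5; HR
9 bpm — chosen so intraclass correlations sit in the 0.15–0.6 range typical
of repeated behavioral measures) and a within remainder, so one
observation's marginal spread equals the configured SD and grand means are
unbiased for the configured means.

Trial construction alternates fixations and saccades until the drawn trial
duration is filled, starting and ending with a complete fixation; the
nominal duration is shifted down by half a mean fixation so realized
durations center on 3600 ms without truncating the final fixation (which
would bias mean durations low). Fixation durations are lognormal
(right-skewed, strictly positive) moment-matched to the configured
mean/SD, resampled above the 100 ms gate plus margin so the ground truth
satisfies the gates it is scored against. Within fixations the direction
jitters isotropically around an anchor (`fixation_noise_deg` = 0.1°,
sub-degree tracker-accuracy scale). Saccades move between anchors along a
great circle with a symmetric triangular velocity profile; a fixed
main-sequence coupling (amplitude = duration × peak velocity / 2, peak
≈ 400 deg/s) keeps peak speeds well above the resulting adaptive thresholds
(~60–80 deg/s), so detectability is physically plausible rather than
assumed. Head traces are AR(1)-smoothed random-walk angle series per axis,
rescaled so the duration-normalized path length equals the drawn per-trial
target exactly — giving exact excursion control and, because the Euler
decomposition is the inverse of the composition used, zero excursion
recovery error by construction.

What the generator does *not* emulate: vestibulo-ocular stabilization,
drift and microsaccades, pupil dynamics, blink kinematics (validity
dropouts default to none; gap handling is exercised by constructed
fixtures), eye–head coupling, and any punch-type effect (none is generated
by default; the configuration accepts per-condition overrides). Passing
recovery tests therefore demonstrates correctness of the measurement chain
under clean, well-specified signal structure — not robustness to every
artifact of real recordings.

Simulation studies of the inference stage (null calibration, power) use a
trial-grain fast path that draws per-trial summary metrics directly from
the generating distributions; the per-trial mean fixation duration inherits
a √m shrinkage of the within spread, m being the expected fixations per
trial.

## Problem sizes used in validation

The recovery and calibration checks run on one default-size study (32 × 2
× 24 trials at 90 Hz, ~500k gaze samples), 1000 null simulations and 200
effect-recovery simulations at the trial grain, and 1000 random velocity
series (≤ 500 intervals) for the exact classifier-vs-enumeration
equivalence. Estimated condition means are reported with
participant-clustered standard errors (SD of participant means ÷ √32),
since trials within a participant are not independent.

## Known limitations

- The between-within df rule, while exact for the balanced paired case, can
  be liberal for heavily unbalanced between-participant contrasts.
- The event detector's duration estimates carry a small positive bias
  (~1–3%) from sample-grid quantization and from sub-threshold saccade
  wings accruing to flanking fixations; this is inherent to threshold
  crossing at finite sampling rates.
- Excursion as path length is sensitive to high-frequency orientation
  noise in real recordings (the generator's traces are smooth);
  `min_step_deg` or pre-filtering should be considered for noisy hardware.
- No area-of-interest analysis, pupil metrics, or covert-attention
  inference: gaze position relative to scene content is out of scope.
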