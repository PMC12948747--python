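# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Data model

A *recording* is one posed expression: a frames × 44 matrix of blendshape
activations in [0, 1] and a frames × 68 × 3 array of landmark coordinates
on a common avatar (arbitrary units, centred at the face centroid).  The
44 analysis channels are the canonical 52 ARKit blendshape names minus the
eight `eyeLook*` gaze channels, ordered alphabetically; that order is
fixed in `facekin.blendshapes` and used in every file the package reads or
writes.  Frame and repetition indices are 1-based in all user-facing
structures.

Two posing conditions are modelled.  *Cued* trials have a fixed length
(default 540 frames ≙ 9 s at 60 frames/s, recorded as metadata only and
never used in computation) and a beeped structure: neutral for the first
third, a ramp to a held peak at the second beep, a return to neutral at
the third.  *Spoken* trials have variable length near a 382-frame mean and
a sustained expression.

## Jerk

Jerk is computed as four successive per-frame differences of the raw
coordinates; each difference shortens the series by one frame, so jerk is
defined over N − 4 timepoints and the first four frames of a trial carry
no jerk value.  Conventional usage sometimes labels jerk the "third
derivative" of position; the operational definition here is the
four-difference chain with its N − 4 valid frames, and that is the
contract the tests pin (382 → 378, 540 → 536).

Per landmark, "absolute jerk" is the Euclidean norm of the 3-axis
fourth-difference vector — invariant to axis order and to global rotation
of the coordinate frame.  A per-axis |·|-then-mean variant
(`combine="absmean"`) is available for sensitivity checks.  No
sampling-interval scaling is applied: jerk is in avatar units per
frame⁴, which is inconsequential for group comparisons on a common frame
rate and keeps the statistic free of an arbitrary time constant.

Spoken recordings are resampled to a uniform length for analyses that
align timepoints.  The default is linear interpolation onto an evenly
spaced grid (endpoints preserved exactly, monotonicity and constants
preserved; the method is pluggable and a cubic spline is provided).  Jerk
is computed on the raw coordinates *first* and the jerk series is then
resampled, to avoid interpolation smoothing the fourth differences.

## Production scores

*Precision* (per participant × emotion × condition × measure): mean over
timepoints per repetition per channel → SD across repetitions per channel
→ mean across channels → negated, so higher = more consistent.  The SD
uses the sample convention (n − 1); a population-SD flag exists.  At
least two repetitions are required.  Because negation is linear, averaging
per-emotion scores before or after negation is equivalent; the package
negates last.

*Differentiation*: per-channel means over repetitions and timepoints per
emotion; per emotion pair, the mean over channels of the absolute
difference; overall, the mean of the three pairs.

*Mean level*: the grand mean over timepoints, channels, repetitions and
emotions, computed as the mean of per-recording means (equal weight per
recording).  For equal-length — i.e. resampled — recordings this equals
the flat mean; for raw variable-length spoken recordings it avoids
weighting repetitions by their duration.

*Recognition accuracy*: per trial, the target-emotion rating minus the
mean of the two non-target ratings (range −10 to 10); per participant, the
mean over trials.

## Mass-univariate inference

Per analysis unit (blendshape or landmark; optionally per unit ×
timepoint), the model is `y ~ 1 + group + TAS` with crossed random
intercepts for subject and repetition number, fitted by REML.  TAS is
centred.  Each fixed effect is reported as sign(β)·√F — the Wald *t* —
so the sign carries the direction of the autistic − non-autistic contrast
(or TAS slope) while the magnitude squared is the F statistic.  (Signed
"F values" appear in this literature; F proper is nonnegative, so the
signed square root is the faithful quantity.)  On convergence failure the
model is refit without the repetition intercept and flagged.

**Engines.**  `fit_unit_model` is the reference fitter (statsmodels
MixedLM).  For complete balanced designs — every subject contributes every
repetition exactly once — the between-subject group and TAS tests collapse
exactly to OLS on subject means: the repetition intercept is common to all
subjects and the subject-mean regression has residual variance
σ²_subject + σ²_resid/R with n_subjects − 3 degrees of freedom, which is
precisely what the REML Wald t estimates when the variance components are
interior.  The collapsed engine (`engine="balanced"`, selected by
`"auto"` whenever the design is balanced) is vectorised across all units
and makes dense permutation studies tractable; tests assert its agreement
with MixedLM to ~1e-3 on the same data.

**Permutation FWER control.**  Group labels are reassigned across
participants (group sizes preserved) and all unit models are refit per
permutation.  The default null pools the maximum |t| across the family
per permutation, and the threshold is the discrete upper order statistic
at 1 − α ("higher" quantile) — the standard finite-permutation
convention, never anticonservative.  One family = one (measure,
condition, emotion, timing mode) slice; in per-timepoint mode the family
spans units × timepoints.  A per-unit pooled mode exists for comparison.
Because relabelling groups does not null a TAS slope, TAS thresholds are
obtained by permuting TAS values across participants within the same
scheme — a documented choice where the original procedure is
underspecified.  Defaults: 1000 permutations, α = 0.05; observed
statistics must strictly exceed the threshold.

Timing modes: `peak` (cued activation at the 1-based peak index, default
270, inside the expression hold), `time_averaged` (mean over timepoints;
for jerk, over the N − 4 valid frames), `per_timepoint` (every unit ×
timepoint, spoken series resampled to the uniform length first).  Peak
extraction is defined only for cued activation, whose fixed beep timing
makes the peak frame comparable across recordings.

## Production → perception

The participant-level feature table holds 12 production features (mean /
precision / differentiation × jerk / activation × cued / spoken) plus AQ,
TAS and IQ, and the recognition-accuracy outcome; groups are analysed
separately.

*Screening* follows the Boruta all-relevant scheme: per iteration, each
feature gains an independently permuted shadow copy; a random forest is
fitted to the augmented matrix; a feature scores a hit when its importance
exceeds the maximum shadow importance.  Hit counts are tested against
binomial(iterations, ½), two-sided: significantly above chance =
confirmed, below = rejected, otherwise tentative (tentatives are left
tentative — no rough-fix pass).  Permutation importance is the default
metric (impurity importance available); the reported mean importance is
the raw importance averaged over iterations, so its scale differs from
Z-scored variants.  Note that with a fixed design matrix a genuinely
irrelevant feature can carry a persistent chance in-sample correlation
and occasionally survive screening — inherent to all-relevant selection,
not a defect of this implementation.

*Sequential regression* enters confirmed features in descending mean
importance; each step's nested-model F-change is tested at α = 0.05
(configurable — reported analyses in this literature have treated
p ≈ 0.051 as "marginal", i.e. a soft rule; this implementation's rule is
hard) and entry stops at the first non-significant step.  Collinear steps
are skipped with a warning.

*Bayes factor*: the entered-predictor model is compared with the
intercept-only null via the Zellner–Siow Cauchy g-prior, computed as a
one-dimensional integral over the g mixing variable in log-space.  The
default Cauchy scale is √2/2; software defaults differ, so the scale is
an explicit argument.  For a single predictor the quantity coincides with
the JZS correlation Bayes factor, which is the independent oracle used in
tests.  Labels follow the conventional ladder: BF₁₀ in (1, 3] weak,
(3, 10] moderate, (10, 100] strong, > 100 extreme; reciprocal values take
the mirrored "for the null" label.

## Synthetic data generator

The generator's defaults are the emulated study design: two groups
(default 25 per group, with asymmetric sizes such as 25 + 26 available),
16 repetitions × 3 emotions × 2 conditions, 540-frame cued trials,
spoken lengths uniform-integer-jittered around 382 frames (emotion-
independent, since no duration difference by emotion is assumed).  Trait
scores are group-conditional normal draws clipped to instrument ranges:
TAS 43.12 (13.58) / 62.24 (12.11), AQ 13.81 (7.62) / 33.24 (9.13),
IQ 116.85 (13.06) / 112.60 (19.88) for the non-autistic / autistic groups.

Activation for one recording is baseline (0.15 resting tone) + emotion
amplitude × temporal template + subject intercept + repetition intercept
+ white residual noise, clipped to [0, 1].  Default noise scales:
subject SD 0.04, repetition SD 0.01, residual SD 0.05 — chosen so that
between-subject variation dominates repetition variation, typical draws
sit well inside the clipping bounds, and reduced-scale mixed models are
comfortably identified.  The cued temporal template uses raised-cosine
ramps (one ninth of the trial, ≙ 1 s of 9 s) between the beeped neutral /
hold / neutral phases: only the beep times are externally constrained, and
the raised cosine gives a smooth, differentiable profile with non-trivial
jerk structure.  Emotion amplitude patterns follow conventional expression
morphology (brow lowering for anger, smile + cheek/eye involvement for
happiness, inner-brow raise + frown for sadness) with peak amplitudes
≤ 0.6.

Ground-truth effects (`EffectSpec`) add a group contrast (autistic
participants only) and a TAS-linear shift (centred at the mid-group TAS
mean, 52.68) inside a chosen channel set and time window, before clipping;
the group-mean contrast at the targeted units therefore converges to the
specified effect as n grows, provided clipping is not engaged.  Jerk
effects are injected as an alternating-sign displacement of amplitude
effect/16 (the fourth difference of a·(−1)ᵗ is 16a·(−1)ᵗ), which adds
approximately the specified magnitude to per-landmark jerk when baseline
jerk is small — approximate because the Euclidean norm is not additive.

Landmarks are a fixed synthetic avatar geometry displaced linearly by the
activations through a fixed coupling tensor, plus white coordinate noise —
smooth trajectories whose jerk inherits the activation dynamics.  Random
intercepts act on the activation scale per channel; landmark variation
arises only through the coupling.

The recognition-task simulator gives each participant a latent
discriminability d = base + slope(group) × z(production score) + noise and
emits 108 trials (36 per emotion, random order) with the target rating
centred at 5 + d/2 and non-target ratings at 5 − d/2, all clipped to
[0, 10].  A feature-table simulator emits the participant-level summary
table directly (with a common factor per measure to emulate the
collinearity of real production summaries), enabling selection-recovery
studies at large n without frame-level simulation.

Determinism: every recording, intercept and trait draw comes from an
independent stream derived from the config seed and the entity's identity,
so identical config + seed is bit-identical, any single recording can be
regenerated in isolation, and the full 4896-recording design streams in
constant memory.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: facial geometry is random rather than
anatomical; activation noise is white (real capture noise is temporally
correlated and heteroscedastic); channels are conditionally independent
given the factors (real blendshapes co-activate along muscle synergies);
spoken trials have no speech-driven articulation; and there is no
idiosyncratic per-participant expression style beyond scalar intercepts.
Tests on this generator validate the estimators and their calibration
under the assumed model, not the substantive findings on captured faces.

## Problem sizes used in validation

Calibration and recovery properties are validated at reduced scale:
null family-wise error uses 200 replicates of 10 participants/group ×
4 repetitions × 20 units × 60 frames with 300 permutations; effect
recovery uses 50 replicates at 15/group with 1000 permutations and an
injected effect of 5 residual SDs at 2 of 44 channels; selection recovery
uses 20 replicates at 200/group with 20 screening iterations of 50-tree
forests.  These sizes keep the full validation suite fast while leaving
each property's sampling error far smaller than the margins being
asserted.

## Known limitations

* The balanced engine requires complete subject × repetition data;
  unbalanced designs fall back to per-unit MixedLM fits, which are orders
  of magnitude slower in permutation loops.
* The exact-recovery probability of a strong localised effect under
  max-statistic pooling is structurally ≈ 1 − FWER (the in-family effect
  inflates the permutation null only moderately), so "exactly the
  injected units and nothing else" cannot exceed ~95–96% no matter the
  power.
* The TAS permutation scheme is a reasoned choice, not a published
  specification.
* Permutation importance is computed in-sample; see the screening caveat
  above.
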