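# facekin

Analysis pipeline for the spatiotemporal and kinematic properties of posed
facial expressions captured with marker-less facial motion capture, aimed at
research comparing expression production between groups (for example
autistic and non-autistic adults) and relating production to emotion
recognition.

A recording is a pair of time series on a common avatar face: 44 blendshape
activation channels (facial action units such as `browDownLeft`, each in
[0, 1] per frame) and 68 tracked 3-D facial landmarks.  From these the
package derives:

* **Jerk** — movement smoothness per landmark, operationalised as four
  successive frame differences of the raw coordinates (position → movement
  → velocity → acceleration → jerk), taken as the Euclidean magnitude of
  the 3-axis fourth-difference vector.  Each difference drops one frame, so
  an *N*-frame recording yields *N* − 4 valid jerk frames (382 → 378,
  540 → 536).
* **Production scores** per participant, condition and measure:
  *mean level* (grand mean over timepoints, channels, repetitions and
  emotions), *precision* (−1 × the across-repetition SD of per-repetition
  channel means, averaged over channels; higher = more consistent), and
  *differentiation* (mean absolute per-channel difference between emotion
  pairs; higher = more distinct expressions).
* **Recognition accuracy** from three 0–10 ratings per trial:
  rating of the target emotion minus the mean of the two non-target
  ratings, averaged over trials.

Inference is mass-univariate: for each channel (optionally each channel ×
timepoint) a linear mixed model

```
y ~ 1 + group + TAS,   random intercepts: subject, repetition
```

is fitted, and each effect is summarised as sign(β)·√F (the Wald *t*).
Family-wise error across channels is controlled by participant-level
permutation: group labels are reassigned across participants, the models
refit, and observed statistics compared with the 95th percentile of the
max-statistic permutation null.  A production→perception stage screens
participant-level features with a shadow-feature random-forest wrapper
(Boruta-style: permuted shadow copies, hits against the max shadow
importance, binomial decisions), enters confirmed features into a forward
sequential regression with an F-change stopping rule, and weighs the final
model against the intercept-only null with a Jeffreys–Zellner–Siow Bayes
factor (labelled weak / moderate / strong / extreme at 1, 3, 10, 100).

A synthetic-data module generates complete studies with this exact
statistical structure — two groups with group-conditional TAS/AQ/IQ trait
distributions, 16 repetitions × 3 emotions × 2 posing conditions (beeped
9-s "cued" trials with a neutral → peak → neutral profile; variable-length
"spoken" trials), crossed subject/repetition random intercepts, and
configurable ground-truth group or TAS effects localised to chosen
channels and time windows — so every stage is testable end to end without
any data download.

## Worked example

Inject a known group difference (autistic − non-autistic = −0.20) on the
two brow-lowering channels of cued anger and recover it at the expression
peak:

```python
from facekin import (EffectSpec, SimulationConfig, generate_dataset,
                     run_mass_univariate)
from facekin.blendshapes import ANALYSIS_BLENDSHAPES

effect = EffectSpec(measure="activation", unit_ids=(0, 1),
                    time_window=(180, 360), emotion="anger",
                    condition="cued", group_effect=-0.20)
config = SimulationConfig(n_per_group=12, n_repetitions=8, frames_cued=540,
                          conditions=("cued",), emotions=("anger",),
                          effects=(effect,), seed=42)
dataset = generate_dataset(config)
result = run_mass_univariate(dataset, measure="activation",
                             condition="cued", emotion="anger",
                             timing_mode="peak", n_permutations=1000,
                             seed=42)
print("threshold:", round(result.thresholds["group"], 2))
for row in result.results[result.results.group_significant].itertuples():
    print(f"{ANALYSIS_BLENDSHAPES[row.unit]}: stat = {row.group_stat:.2f}")
print("percent significant:",
      round(result.percent_significant["group"], 2))
```

prints

```
threshold: 3.81
browDownLeft: stat = -9.64
browDownRight: stat = -11.61
percent significant: 4.55
```

Exactly the two targeted channels exceed the permutation threshold; the
negative statistics recover the injected direction (lower activation in the
autistic group), and 2 of 44 channels = 4.55% of the family is flagged.

A command-line interface wraps the same stages
(`facekin simulate | jerk | scores | massuni | select | all`); run
`facekin all --seed 7 --out demo_run` for an end-to-end demonstration on a
small simulated study.

## Layout

| module | contents |
| --- | --- |
| `facekin.blendshapes` | canonical 52-channel list, gaze exclusion, fixed 44-channel analysis order |
| `facekin.types` | `ParticipantMeta`, `Recording`, `EffectSpec`, `SimulationConfig`, `JerkSeries` |
| `facekin.synthetic` | study generator, recognition-task simulator, feature-table simulator |
| `facekin.kinematics` | successive differences, jerk, resampling, peak extraction |
| `facekin.scores` | precision / differentiation / mean level / recognition accuracy |
| `facekin.massuni` | per-unit mixed models, balanced collapsed engine, permutation FWER |
| `facekin.perception` | shadow-feature selection, sequential regression, JZS Bayes factors |
| `facekin.io`, `facekin.pipeline`, `facekin.cli` | CSV/YAML/JSON formats, orchestration, CLI |

See `docs/methods.md` for the statistical model, design choices and known
limitations.
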