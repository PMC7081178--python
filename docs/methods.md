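# Methods

## Task

The simulated task is the unambiguous card-sorting variant: four fixed
target cards (one red triangle, two green stars, three yellow crosses,
four blue circles) and a 24-card stimulus deck containing exactly those
cards whose colour-, shape- and number-matching targets are pairwise
distinct. Every deck card therefore shares exactly one feature with each
of three targets and none with the fourth, so the sorting rule a
participant applied is readable from the response alone. Sessions use 64
cards (shuffled whole-deck copies, truncated) and a criterion schedule:
after 10 consecutive correct sorts a category is credited and the rule
switches covertly to one of the other two rules, chosen uniformly. A
random-run schedule (run length uniform on {2,3,4,5}, median 3.5) is
available for frequent-shift administrations.

Errors are classified per trial: **PE** (perseverative) — the response
applies the previously successful rule despite negative feedback on the
previous trial; **SL** (set loss) — the response changes rule despite
positive feedback on the previous trial; **IE** (integration) — after
negative feedback, the newly adopted rule was already excluded by negative
feedback on one of the two preceding trials; everything else scores
`other_error`. Only negative feedback is used as exclusion evidence for
IE: right after a covert rule switch, the stale positive feedback of the
completed run would otherwise "exclude" both remaining rules and mislabel
ordinary exploration. Omissions (cycle cap reached, default 1000) receive
no feedback and are excluded from response-time averages.

## Network

Each schema node (3 cognitive, 4 sensorimotor) integrates its input with a
first-order low-pass filter (smoothing constant δ = 0.6) and squashes it
with a logistic of gain α and threshold β. Cognitive nodes receive a
constant drive o_ext = 0.75 plus their thalamic feedback; sensorimotor
nodes receive the stimulus (o_stim = 0.5 plus a per-trial uniform noise
draw, U(−0.2, 0.2), shared by the matching nodes), the rule-routed drive
w_rule · o_cog from the selected cognitive schema, and thalamic feedback.
Each node's basal-ganglia channel computes, per cycle,

    D1/D2:  u = o_ctx                    (β adapted; gain 8.5)
    STN:    u = 1.2 o_ctx − 1.0 o_gpe(t−1)
    GPe:    u = 0.9 Σ_j o_stn,j − 1.0 o_d2(t−1)
    GPi:    u = 0.9 Σ_j o_stn,j − 0.3 o_gpe − 1.0 o_d1
    THAL:   u = o_gpi,  o = −σ(a)        (output in (−1, 0))

with all nucleus gains 8 and thresholds (STN 0.30, GPe 0.25, GPi 0.25,
thalamus 0.45). The Σ_j sums run over all channels of the loop (diffuse
STN projection); the cognitive (3-channel) and sensorimotor (4-channel)
complexes are fully segregated. Within a cycle, the cognitive layer is
updated first (it reads the previous cycle's thalamic output), the
sensorimotor layer reads the current cognitive outputs, and each
basal-ganglia complex reads the current cortical outputs; STN reads the
previous cycle's GPe and GPe the previous cycle's D2, per the update
equations.

## Selection and timing

A schema is selected when its output exceeds θ_s = 0.5 and its
accumulated output area reaches an integration threshold drawn from
N(4000, 400²), truncated positive, independently per node. The published
threshold scale is large relative to the area a node actually accumulates
in a trial, so a calibration constant maps accumulated area onto the
threshold scale. For the sensorimotor layer this constant (`area_scale`)
was set once by bisection so that the default model's mean response time
on post-positive trials is ~129 cycles (the packaged value is 33.39); the
post-negative response time and all other statistics are untouched by the
calibration. The sensorimotor integrators reset at each stimulus onset.

The cognitive integrator is not tied to trials: a selected rule schema
persists across trials while its output holds above θ_s, and the area
gating (re)selection accumulates from the last deselection with its own
scale (`area_scale_cog` = 300), making task-set re-adoption cost a modest
fraction of a response time rather than a full trial. Per-node threshold
draws double as the competition's tie-breaker: the threshold clipping of
the learning rule (below) regularly leaves channels with bit-identical
state, and without independent accumulator noise a deterministic
lowest-index tie-break permanently starves one rule.

Two state resets shape the trial structure, both adopted after the
persistent-loop alternative proved behaviourally degenerate (the
winner-take-all state of a loop is bistable per channel, so yesterday's
winner otherwise answers today's card whenever it shares a feature):

* **act completion** — when a sensorimotor schema is selected, the
  response is emitted and the whole sensorimotor layer and its channel
  complex reset to rest, releasing the competition for the next card;
* **post-error interrupt** — negative feedback resets the cognitive layer
  and its complex, so re-selection is decided by the updated striatal
  thresholds rather than by the incumbent's activation advantage. After
  positive feedback the cognitive loop is untouched.

A feedback-processing interval of 10 cycles (no stimulus; both loops keep
cycling) separates feedback from the next card. It represents motor
execution and feedback evaluation, and it gives the interrupted cognitive
competition time to re-sort before the next sensorimotor race begins;
without it the race locks in before the re-adopted rule can bias it and
post-error responding becomes stimulus-random. Residual re-sorting spills
into the next trial, producing the post-error response-time cost.

## Learning

After each feedback event r ∈ {+1, −1}, every cognitive channel i updates
its striatal threshold:

    f_i   = +1 if rule i is consistent with the response,
            (2 w_neg − 1) − m_r · f_prev,i · r_prev,i otherwise
    δ_i   = r (f_i − median_i)          (median output over the trial)
    β_i  ← clip[(β_i − ε_str δ_i)(1 + ζ), 0, 1],   ζ ~ U(−0.1, 0.1)

The D2 threshold mirrors the adapted D1 threshold (β_d2 = 1 − β_d1,
configurable to `shared` or `fixed`): dopamine moves the two populations'
excitability in opposite directions, and with a shared threshold the
indirect pathway largely cancels the direct pathway's learned signal,
leaving the rule competition unresolved. Sensorimotor striatal thresholds
stay fixed at 0.5. The sensorimotor gain updates once per feedback event,
α_sma ← (1 + ζ) Π_i (1 + ε_sma + o_i), with ζ ~ U(−0.1, 0.1).

Defaults: ε_str = 0.40, ε_sma = 0.50, w_neg = 0, m_r = 0. Virtual
Parkinson's-disease groups reduce ε_str to 0.10 (PD_1) and additionally
raise w_neg to 0.65 (PD_2), m_r to 0.60 (PD_3), or both (PD_4). The
four-dimensional group spaces used for grids and midpoints are
HC: ε_str 0.40–0.70, ε_sma 0.50–0.70, w_neg 0.00–0.20, m_r 0.00–0.20;
PD: ε_str 0.05–0.20, ε_sma 0.30–0.50, w_neg 0.50–0.80, m_r 0.50–0.70.

## ERP proxies

The ERN proxy is the negated extreme one-step change across sensorimotor
outputs; the SPP proxy the (un-negated) extreme one-step change across
cognitive outputs. Cycles whose one-step difference is an administrative
reset (act completion, post-error interrupt) are masked: the proxies
measure loop dynamics, not bookkeeping. The ERN is response-locked
(window 20 cycles before to 40 after, baseline the 10 preceding cycles);
each outcome class is summarised by the signed extreme deviation of its
mean trace from baseline, and the session's ERN attenuation is the
correct-class extreme minus the incorrect-class extreme (clearly negative
when the error response dominates; attenuation moves it toward zero). The
PSP contrasts the peak SPP on shift trials (first trial after negative
feedback with a changed selected schema) against the first post-shift
trials, with trial epochs running stimulus-to-next-stimulus so each trial
owns its own feedback-processing transient. PSP is reported undefined for
sessions without any shift.

## Randomness and reproducibility

A master seed spawns independent named streams (deck order, stimulus
noise, striatal noise, gain noise, integration thresholds, rule choices),
so sessions are bit-reproducible and changing one noise source leaves the
others' draws unchanged. Group drivers spawn one child seed per session.

## What the simulations do and do not show

The generator's defaults are the study conditions: 64-card sessions,
criterion-10 schedule, 100 sessions per behavioural table, 20 per ERP
group, grids of 4⁴ points × 10 runs (scaled-down grids are used in tests
and the acceptance script: 2⁴ × 5). The model reproduces the qualitative
structure of the task: high sorting accuracy with ~4–5 categories under
default parameters, perseveration strongly elevated by reduced ε_str
without elevated set loss (PD_1/PD_3), set loss appearing only through
blunted negative-reward sensitivity (PD_2/PD_4), slower responding after
negative feedback in every group, ERN and PSP proxies attenuated at the
PD midpoint relative to the HC midpoint, an ε_sma effect on the ERN but
not the PSP, and a strong, near-constant negative lagged coupling between
GPi and sensorimotor output across the whole ε_sma range (selection is
independent of the conflict-gain mechanism).

Known quantitative limitations, documented rather than patched:

* With the threshold-update rule as published and clipping to [0, 1], the
  non-selected rules' thresholds sit at the ceiling throughout a correct
  run, and re-sorting after a covert switch needs ~2 negative-feedback
  events more than the published means imply. Default-run perseveration
  is therefore ~8.5 rather than ~5.4, and PD_1's ~18 rather than ~12; the
  orderings between groups are preserved.
* Set-loss errors at default parameters are structurally absent under the
  shared-stimulus-noise reading adopted here (the alternative, per-node
  noise, produces set loss in every group including PD_1 and breaks the
  perseveration/set-loss dissociation; we preserve the dissociation).
* The ERN group contrast is carried by ε_sma rather than ε_str in this
  implementation: the sensorimotor race resolves early in the trial, so
  response-time conflict — and with it the ERN — is insensitive to the
  striatal learning rate.
* PSP attenuation falls as severity rises across the PD grid, so its rank
  correlation with perseveration is negative here, not positive.

Degenerate inputs: `n_trials < 1`, empty group specifications, even
smoothing windows, constant vectors for min-max normalisation and
correlations on fewer than three points are rejected with `ValueError`;
undefined PSP values and empty ERN classes are returned as `None` and
excluded pairwise from group statistics.
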