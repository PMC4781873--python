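# Methods

## The experiment being emulated

Seven within-subject conditions: localization alone with visual (VI),
tactile (TA) or congruent visuotactile (VITA) location cues; visual
search alone (VS); and the three dual-task pairings (VI+VS, TA+VS,
VITA+VS). A localization-only trial lasts 11 s and carries 4–5 location
cues of 600 ms duration with at least 1 s between onsets; each cue points
in one of 8 compass directions and is answered on the numeric keypad
(8 = up, 6 = right, 2 = down, 4 = left, diagonals on 7/9/1/3). The search
display holds 20 items, the target is present on half the trials, and the
observer self-terminates the search. In dual-task trials cues keep
arriving for as long as the observer searches and stop at search
termination (the trial's "active interval"). The experiment is 21 blocks
of 10 trials; every consecutive set of 7 blocks contains each condition
once and no condition repeats across adjacent blocks. The default cohort
is 12 subjects.

## Generative model

**Cue schedules.** Onsets are uniform on the feasible region given the
minimum 1 s inter-onset gap and the requirement that the last cue end
inside the active interval (sorted uniform draws on the slack, shifted by
the gap). Cue counts are drawn uniformly from 4–5 for an 11 s trial and
scale pro rata with the active interval in dual trials, capped by
feasibility; very short searches can legitimately carry zero cues.

**Localization responses.** A cue is detected with a per-modality
probability; detection emits a response whose direction is the true
direction plus von Mises noise, binned to the nearest of the 8
directions, at a lognormal latency from cue onset. Dual-task load
subtracts a fixed amount from the detection probability and multiplies
every concentration by a factor ≤ 1. In the default `fusion` mode the
VITA concentration is `κ_VI + κ_TA`: precisions add, which is exactly the
generative analogue of MLE fusion, and the load factor preserves it
(`(κ_VI + κ_TA)·f = κ_VI·f + κ_TA·f`). The `best_cue` control mode sets
the VITA concentration to `max(κ_VI, κ_TA)`, i.e. no integration — the
optimality assessment must fail on such a cohort.

**Search.** Serial self-terminating search with exponential per-item
inspection times. The mean item time is a base value plus a per-item
dual-task penalty that depends on the concurrent localization modality
(largest for visual localization, equal and smaller for tactile and
visuotactile). A present target is overlooked with a small probability at
its inspection, in which case the display is exhausted and the trial ends
as a miss; absent targets always end in correct rejection (no
false-alarm channel — search accuracy errors come from misses only).

**Gaze.** Per-trial median gaze deviation is a folded-normal draw
|N(0, σ_gaze)|, constant across conditions.

**Seeding.** One master seed; subject `i` uses the stream
`SeedSequence(seed, spawn_key=(i,))`, so any subject is reproducible in
isolation and cohorts are bit-reproducible. Cohort heterogeneity applies
multiplicative lognormal jitter (default CV 0.15) to concentrations, item
times and mean latency, iterating parameter dictionaries in sorted key
order so the draw-to-parameter assignment is invariant to how a config
file ordered its keys.

## Default parameters and why

| parameter | default | rationale |
|---|---|---|
| κ_VI, κ_TA | 6.0, 3.0 | chosen by a pre-implementation quadrature study of the *discretized* von Mises error: visual more reliable than tactile, plausible accuracy levels (≈0.65/0.48 correct; fused ≈0.75), and a population fused-to-predicted variance ratio of 0.99 so that precision summation survives 8-direction binning |
| p_detect (VI/TA/VITA) | 0.92 / 0.90 / 0.95 | high single-task detection with a small bimodal benefit |
| dual_detect_penalty | 0.18 | a large, unambiguous main effect of task on detection |
| dual_kappa_factor | 0.7 | load inflates error variance at both unimodal and bimodal sites; population fused ratio under load 0.955 |
| base_item_time_s | 0.25 s | search-alone medians of ~4 s over 20 items |
| dual_item_penalty_s (VI/TA/VITA) | 0.20 / 0.12 / 0.12 s | interference of a few seconds, largest when both tasks are visual, tactile ≈ visuotactile |
| p_miss_target | 0.10 | search accuracy near but below ceiling |
| rt_mean_s, rt_sd_s | 0.55, 0.15 s | lognormal latencies comfortably inside the ≥1 s inter-onset gap |
| gaze_sd_deg | 0.78 | mean per-trial median deviation ≈0.62°, safely below the 1° fixation screen |

These defaults are the package's study conditions; analyses and tests run
against them unchanged.

## Analysis conventions

* **Direction coding.** 0° = up, clockwise positive; signed angular error
  wrapped to (−180°, +180°]; exact opposition is +180° by convention so
  the error set is exactly {0, ±45, ±90, ±135, +180} and variances stay
  well defined.
* **Hit assignment.** The response window of cue *i* is
  [onset_i, onset_{i+1}); the last window extends to the end of the active
  interval (trial duration, or search termination in dual trials). The
  first response in a window is paired with the cue; extra responses in
  the window are ignored; responses before the first onset or after the
  active interval are discarded with a logged count.
* **Cell statistics.** Detection performance = paired cues / all cues;
  localization accuracy = correct / paired (misses excluded from the
  denominator — zero hits is signalled, never reported as 0); error
  variance = sample variance (n−1) of signed errors of all paired
  responses, correct responses contributing 0°; reaction times are means
  over correctly localized cues, measured from cue *onset*; search times
  are summarized per subject by medians (midpoint rule on even counts).
  Cells whose measure is undefined stay missing, never zero-filled.
* **Missing data.** The optimality assessment drops subjects with a
  missing variance cell (logged); variances are computed from detected
  cues only, with nothing imputed for misses.
* **ANOVA engine.** Balanced complete subjects × cells matrices; sums of
  squares by the standard within-subject partition (verified to decompose
  the total exactly). Sphericity per effect from the sample covariance
  (n−1 divisor) of orthonormal Helmert contrasts — main effects on data
  collapsed over the other factor, the interaction via the Kronecker
  product of factor contrasts. Mauchly's p uses the chi-square
  approximation with the standard second-order term (as in ezANOVA);
  Greenhouse–Geisser ε̂ = tr(S)²/(d·tr(S²)), clipped to [1/d, 1]. The GG
  correction is applied per effect only when that effect's Mauchly test
  rejects at α; two-level effects are spherical by construction (W = ε =
  1), so their dfs are reported uncorrected.
* **Normality gate.** Shapiro–Wilk on pooled cell-mean-centered residuals
  at α = 0.05; on rejection the dependent variable is replaced by its
  natural log, which requires strictly positive values. The pipeline
  falls back to the untransformed analysis with a logged warning when a
  legitimate zero cell (e.g. an error-free variance cell) blocks the
  transform; calibration studies of the F machinery run with the gate off,
  since null Gaussian data trigger it spuriously ~5% of the time and
  cannot be log-transformed.
* **Multiplicity.** Each set of comparisons reported together (e.g. the
  three modality pairs of one post-hoc analysis, or the four gaze screens)
  forms one Holm–Bonferroni family. All tests are two-sided.
* **Optimality report.** Per subject and load: unimodal variances, the
  MLE prediction, the observed bimodal variance and their ratio, plus the
  weaker qualitative criterion (observed below both unimodal variances).
  Group level: means, ratio of means, the fraction meeting the qualitative
  criterion, and — as a formal extension of the usual descriptive
  comparison — a paired t-test of observed against predicted. Figure
  error bars are SEMs over per-subject values (predictions computed per
  subject, then aggregated).

## What the simulator does and does not emulate

It reproduces the *statistical shape* the analysis assumes: condition
structure and block schedule, cue timing constraints, discrete keypad
responses with modality-dependent reliability, detection and reliability
costs of dual-task load, modality-dependent search slowdown, early
termination on present targets, and gaze summaries below the fixation
threshold. It does not model eye-movement dynamics, vibromotor physics,
learning or fatigue across blocks, criterion shifts in the search task,
response-latency differences between modalities, or incongruent cue
pairs (cues are always congruent, so cue weights are unidentifiable by
design and are not estimated). Passing tests therefore certify the
analysis chain and the recoverability of its effects at realistic sample
sizes — not any claim about real observers.

## Numerical and scale choices in the tests

The end-to-end optimality check uses one default cohort (12 subjects × 30
trials per condition, master seed 0) and a 10% band on the group
observed/predicted ratio; at this scale the ratio carries ~7% sampling
scatter (variance estimates from ~60–120 errors per cell), which the band
accommodates around population values of 0.99 (single) and 0.955 (dual).
The generator-level fusion invariant is additionally checked at 10,000
detected cues per cell, where sampling error is ~2%. Calibration checks
(Mauchly and ANOVA type-I rates, t-test null rates) use 500–1,000 seeded
replicates at n = 12; oracle-equivalence checks compare against pingouin
and an independent orthonormal-contrast GLM computation on fixed
fixtures. The full suite runs in well under a minute on one CPU.

## Known limitations

* Discretization to 8 response directions biases the fused-variance ratio
  a few percent below the continuous MLE prediction at low concentrations;
  the defaults were chosen where this bias is small, but very unreliable
  observers (κ ≲ 2) would show it.
* The Greenhouse–Geisser ε̂ uses the n−1 covariance divisor; software
  differs here, and reported ε (hence corrected dfs) can differ in the
  third decimal across packages.
* The search model is phenomenological: exponential item times and a
  single miss probability reproduce the qualitative orderings (present
  faster than absent; visual-localization load slowest) but are not fit
  to any process theory of search.
* With very small cells (few detected cues) variance cells can be
  legitimately zero or missing; the pipeline degrades gracefully
  (fallback to untransformed analysis, logged subject drops) rather than
  imputing.
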