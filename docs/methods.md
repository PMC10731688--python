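# Methods

This note documents the models, conventions and numerical choices behind
`screeneval`, and what a green test establishes (and does not) about them.

## Unit of analysis and data model

The unit of analysis is the screening examination, not the woman: a woman
screened in successive rounds contributes several exams, and no clustering
adjustment is applied (matching how programme-level accuracy audits are
normally tabulated). A cohort is a flat table with one row per exam: reader
decisions coded {0 = normal, 1 = recall}, an optional recorded arbitration
(empty = absent), an AI exam score in [0, 10] kept at five decimals, and an
optional cancer record (diagnosis offset in days, next-screen offset, and
tumour attributes). Tumour size, grade, TNM, nodal status, ER and HER2
apply to invasive cancers only and must be absent or "unknown" for DCIS.
Unknown subgroup labels form explicit "unknown" strata. Ages outside the
core 50–69 programme range are retained.

A recorded arbitration may coexist with reader agreement (a small fraction
of exams acquire a decisive third read through side channels such as
stereotactic biopsy disagreements); the combined reading rule honours the
recorded arbitration in that case.

## Reference standard

An exam is positive under the primary standard when a histopathologically
verified breast cancer (invasive or DCIS) is

* attributed to the index screen's recall work-up — encoded as
  `dx_offset_days == 0`. Encoding attribution as day zero, rather than a
  small positive window, removes ambiguity against very early interval
  cancers; for cohorts recorded differently, a labelling option
  (`recalled`, `recall_attribution_days`) re-attributes cancers diagnosed
  within a chosen number of days of a *recalled* exam; or
* an interval cancer: `0 < dx ≤ min(window_days, next_screen − 1)` with
  `window_days = 730` by default. The 12-month split is right-open at 365
  days. Windows are half-open in days because source tabulations state
  months only; the day-level convention must be fixed somewhere and is
  configurable.

The extended (exploratory) standard additionally counts next-round cancers
(`dx == next_screen`, the diagnosis attributed to the subsequent screen's
work-up, mirroring the day-zero convention) and long-term cancers
(`730 < dx ≤ 7·365` days) as positive. Re-scoring under the extended
standard changes only the truth labels; scenario decisions are not
re-simulated. A corner case stays negative under both standards: a cancer
diagnosed after an early next screen (< 730 d) but neither at that screen
nor more than two years out.

## Threshold calibration

Recall is strict: `score > threshold`; the boundary score is normal.
Candidate thresholds are the distinct observed scores plus a sentinel one
unit below the minimum (the all-recall point), so both a perfect-sensitivity
and a perfect-specificity target are always attainable; consequently the
sentinel may fall below 0 when the minimum score is 0. The default
"guarantee" rule returns, among thresholds whose constrained metric is at
least the target, the one maximising the complementary metric, ties broken
toward the larger threshold (fewer recalls). Because the empirical ROC is a
step function, the matched sensitivity can overshoot its target by at most
one step (1/n_pos) — which is why a matched scenario reproduces the
reader's printed sensitivity to one decimal on large cohorts. A "nearest"
rule (closest achievable constrained metric) is available, since published
analyses rarely state which convention was used. Thresholds are carried at
full floating precision and never rounded internally.

## Scenario engine

Four scenarios are produced over the same cohort: first reader alone,
combined reading (the recorded historical outcome, reproduced exactly),
standalone AI (no arbitration pathway exists; workload of zero human
reads), and integrated AI. The integrated rule per exam: if the AI decision
equals the second reader's, that decision stands (no arbitration, even for
historical-overlap exams — a flag enables the alternative of counting and
applying those recorded arbitrations); on disagreement, the recorded
arbitration is applied when one exists, regardless of why it was originally
performed; otherwise a simulated arbitrator decides.

The simulated arbitrator is deliberately minimal: a single Bernoulli draw
per needed exam, conditioned on truth only — `P(recall | cancer)` equals
the historical arbitrator's sensitivity and `P(normal | non-cancer)` its
specificity, both estimated from the recorded arbitrations against the
chosen reference standard. Richer conditioning (on the AI score, reader
patterns, or subgroup) cannot be identified from accuracy-level summaries,
so only the overall operating point is matched. Draws are consumed in
`exam_id` order from a named seed; by default each (scenario, threshold
mode) derives its own sub-stream from the base seed so threshold variants
are not artefactually coupled (`share_draws=True` reuses one stream).

Workload accounting: human reads = 2 per exam + 1 per arbitration for
combined reading, 1 per exam + 1 per arbitration when AI replaces the first
reader, 1 per exam for the first reader alone, 0 for standalone AI.
Relative workload deltas are reported against the comparator's recall and
arbitration counts.

## Statistics

All estimates are exact ratios of integer counts; percentage rendering
(one decimal, p-values to two significant figures with a "<0.0001" floor)
is presentation-only. Intervals are 95% Clopper–Pearson, computed from beta
quantiles (`low = B(α/2; k, n−k+1)`, `high = B(1−α/2; k+1, n−k)`), the
standard inversion of the binomial tails; tests verify the endpoints invert
the tails to 1e-10 and that empirical coverage is conservative.

Paired comparisons on the same exams use McNemar's test on the discordant
cells `b, c`: exact two-sided binomial `Bin(b+c, ½)` when `b + c < 25`
(the "too small" cutoff is configurable; 25 is the common rule of thumb),
otherwise the asymptotic `χ²₁ = (b−c)²/(b+c)` without continuity correction
(the corrected variant is available, as software defaults differ).
`b + c = 0` yields p = 1.

Sensitivity and specificity are compared on the positive/negative subsets
respectively, the arbitration rate on paired arbitration indicators, and
the secondary proportion endpoints by exact McNemar-style binomial tests on
paired indicators: the recall indicator for the recall rate, and
correctness-given-recall for PPV (correctness-given-clearance for NPV).
For PPV/NPV the pairing is genuinely under-determined: restricting to
exams recalled by *both* scenarios makes the two correctness indicators
identical under a shared reference standard, so that variant is degenerate
(p = 1) and is reported for completeness; the informative variant pairs the
recalled-and-correct indicator over exams recalled by *either* scenario.
Both are surfaced and labelled rather than silently chosen. No multiplicity
correction is applied across the subgroup tests.

Subgroup detection tables report detected/total true cancers per cancer
category (screen-detected; interval, split at 12 months) and per tumour
characteristic (invasive cancers only for size, grade, TNM, nodes, ER,
HER2), each with a paired p-value against the reference scenario using the
same small-cell exact fallback. Cross-tabs count cancers detected by both,
either, or neither scenario; their marginals equal the scenarios' detected
totals by construction.

## Synthetic cohort generator

The generator states a world; its defaults are fixed and are not tuned to
test outcomes:

| parameter | default | note |
|---|---|---|
| prevalence | 0.0079 | within-window cancers per exam |
| screen-detected fraction | 0.725 | of cancers |
| interval <12 m fraction | 170/562 | of interval cancers |
| reader 1 operating point | (0.637, 0.978) | marginal over all cancers |
| reader 2 operating point | (0.70, 0.978) | |
| raw inter-reader agreement | 0.973 | drives the copula correlation |
| arbitrator operating point | (0.80, 0.90) | recorded arbitrations |
| overlap fraction | 426/251,089 | concordant exams with a recorded arbitration |
| AI score, non-cancer | 10·Beta(2, 5) | right-skewed, low |
| AI score, screen-detected cancer | 10·Beta(12, 1.2) | concentrated near 10 |
| interval-cancer visibility | 0.25 | weight on the cancer-like component |
| next screen | 730 d | biennial programme |

Reader dependence uses a shared Gaussian latent (a Gaussian copula): each
reader recalls when its latent, correlated at ρ with the shared factor,
falls below the class-specific marginal quantile. ρ is solved by Brent root
finding on the agreement curve, with the bivariate-normal rectangle
probability evaluated by fixed-order (200-point) Gauss–Legendre quadrature
— deterministic and accurate to well below the solver tolerance. Agreement
targets outside the attainable range (independence floor to the
comonotone ceiling `1 − Σ w·|p₁ − p₂|`) raise an error stating the range.
This is the minimal dependence model consistent with reported marginal
accuracies and raw agreement; the true joint dependence (including any
coupling between the AI score and reader errors) is unknowable from such
summaries, so the AI score is class-conditionally independent of the
readers by default.

Interval cancers draw their AI score from a mixture leaning toward the
non-cancer component with visibility weight 0.25, chosen once so that a
standalone AI at a matched threshold detects roughly a fifth to a quarter
of interval cancers — the observed order of magnitude when screening AI is
evaluated against interval outcomes. Optional next-round and long-term
classes (default off) add cancers beyond the window to exercise the
extended standard. Arbitration decisions are drawn from the arbitrator
operating point conditioned on truth, for every reader disagreement plus
the small overlap fraction of concordant exams.

What the generator does **not** emulate: the definitional coupling of
registry data whereby combined reading detects *every* screen-detected
cancer (here reader decisions and outcome category are drawn
independently, so the synthetic combined reading can miss a day-zero
cancer); reader behaviour change under AI assistance; tumour growth and
screening-round dependence within a woman; subgroup-specific detectability
(labels are sampled independently of the AI score by default, with a hook
for subgroup shifts). A green end-to-end test therefore establishes that
the pipeline's estimators, calibration, simulation and paired tests are
correct on a cohort with the stated marginal structure — not that any
particular real-world accuracy value is reproduced. With the stated beta
score models the synthetic AI separates classes far more cleanly than any
real system, so absolute scenario estimates (e.g. standalone specificity)
are not comparable to published figures and are exercised only through
structural identities and parameter-recovery checks.

## Degenerate inputs and errors

Calibration requires both classes (and a target in (0, 1]); arbitrator
estimation requires at least one arbitrated exam of each truth class and
otherwise asks for an explicitly supplied operating point; historical
cohorts must be complete (a reader disagreement without recorded
arbitration is an itemised error — simulated arbitration exists only inside
the integrated scenario); negative diagnosis offsets are rejected with the
offending exam ids. Empty subgroup levels yield rows with total 0 and no
test. All-equal scores yield exactly the two degenerate ROC points.

## Reproducibility

Every stochastic step is driven by an explicit seed: the generator from
`GeneratorParams.seed`, simulated arbitration from the run seed via stable
per-scenario sub-streams. Re-running a configuration reproduces every
number bit-for-bit; run headers record the seed, both thresholds at five
decimals, and the count of observed vs simulated arbitrations per scenario.
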