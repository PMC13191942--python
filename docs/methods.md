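# Methods

## Coding model

The observational record is a three-channel step process.  At every instant
a child has exactly one state on each channel — object in mouth, location,
risk context — and a coder's button press at time *t* moves its channel
into the pressed state until the next press on that channel.  We represent
this as half-open intervals `[start, end)` per channel; the half-open
convention makes boundary instants unambiguous, keeps adjacent intervals
disjoint, and lets every duration query reduce to exact interval
intersection (no per-second discretization anywhere in the production
path; a per-second brute-force tabulation exists only as a test oracle).

A **mouthing contact** is a maximal run of a non-sentinel object state.
Two consequences follow from the coding semantics:

- a change of object without an intervening `Nothing` is two contacts
  (the coder re-pressed because the object changed);
- a repeated press of the *same* object with no `Nothing` between is
  indistinguishable from a continued contact and is merged.  This may
  undercount very rapid same-object re-contacts; nothing in the record
  can separate the two readings.

Only one object can be coded at a time.  When several objects are mouthed
simultaneously the palette's priority order decides: states are listed in
descending risk within each channel, and `resolve_priority` returns the
lowest-ranked (highest-risk) candidate.  This resolution happens at coding
or simulation time; the interval engine never sees multi-object states.

The palette is data, not code.  The shipped default has 35 object states
(12 high-risk, 12 fomite, 7 food, 2 own hand/skin, 2 other people's
hand/skin), 8 locations (5 outdoor — porches count as outdoor — and 3
indoor) and 6 contexts (3 high-risk: near feces, near animals, interacting
with environmental water; plus eating, handwashing, no-risk).  The named
high-risk objects are ordered first; the relative order of the remaining
buttons is a package convention, configurable per study.  Studies in other
settings are expected to adapt the high-risk definitions to local
conditions by shipping their own config.

## Metrics

Analyses are per child.  When a child appears in both campaigns the counts
and durations are pooled first and a single rate is formed (`count /
child's own observed hours`), which weights by observation time; rates are
never averaged across campaigns.

- Mouthing frequency: contacts per hour observed, overall and per object
  group.
- Durations: minutes per hour observed in each location/context
  (`60 * stratum_s / observed_s`), so values live in [0, 60].
- Conditional (stratum) rates: contacts whose *onset* falls in the stratum
  divided by the child's time in the stratum.  Onset attribution keeps the
  four location x context cells additive to the child's total; an
  any-overlap attribution would not.  A child never observed in a stratum
  gets a *missing* conditional rate, not zero, and is excluded from that
  stratum's denominator in cohort tables.
- `NotInView` handling: by default "hour observed" means *observable* time
  — OBJECT-channel `NotInView` intervals are removed from every
  denominator (including their three-way overlap with location x context
  cells).  The alternative reading (gross video duration) is available via
  `exclude_not_in_view=False` / `--include-not-in-view`; switching
  denominators can only move rates, never counts.  Camera pauses appear
  only as clip boundaries and contribute zero observed time; channel state
  never persists across a clip boundary (each clip restates all channels
  at t = 0).

Cohort tables report n, % of children observed (denominator: all children
in the cell, or children with stratum time for conditional measures),
mean, SD (ddof = 1), median, IQR as the single width Q3 − Q1, and max.
Quantiles use the linear-interpolation convention (numpy default).
Eating-related shares are emitted in both readings — pooled contact-count
share and child-averaged share — since they differ whenever children
contribute unequal contact counts.

## Reliability QC

ICC(A,1), the two-way absolute-agreement single-measure coefficient, is
computed from the two-way ANOVA decomposition

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))

with MS_R between-clip, MS_C between-coder, MS_E residual mean squares
(residuals computed directly, not by subtraction, so perfect agreement
scores exactly 1.0).  An all-equal matrix has zero total variance and is
defined as 1 with a warning.  The proficiency gate passes only if every
assessed parameter reaches ICC ≥ 0.75; the default parameter set is
per-clip any-mouthing count, food-contact count, outdoor seconds and
high-risk-context seconds (configurable — the assessed set is a study
choice).  Double-coding samples 15% of clips uniformly, seeded.

Random checks of rare high-risk codes stop (and errors are corrected) once
`(coverage ≥ 20% OR ≥ 10 clips) AND clip error rate ≤ 0.3`; reviewing
every clip exhausts the search regardless of rate.  The error-rate
denominator is clips, matching the rule's clip-level phrasing; an
event-level variant can be built by redefining what a clip "error" is
(the CLI's default marks a clip erroneous when the coder's high-risk
context seconds or high-risk object count disagree with the reference
record).

## Statistical tests

Wilcoxon rank-sum: two-sided, statistic = rank sum of the first group
under midranks.  With pooled n ≤ 12 and no ties the null distribution is
enumerated exactly; otherwise a tie-corrected normal approximation with
continuity correction is used (which of the two the original analyses
used is not knowable, so the result records its method).  Chi-square for
2×2 tables applies Yates' continuity correction, flooring |O − E| − 0.5 at
zero, and refuses tables where any expected cell is below 5 (more than
20% of a 2×2's cells).  The planned grid — within-country age, mobility
(walking-only vs pre-walking), sex and location contrasts; between-country
rate and outdoor-time contrasts; chi-square of age/sex against the
high-risk-context indicator — applies no multiplicity adjustment; the
report prints how many tests ran.  The indoor-vs-outdoor rate comparison
treats per-child conditional rates as independent samples (the primary
specification), although the data are within-child; a paired signed-rank
variant sits behind `paired_location=True` for sensitivity analysis.

## Synthetic cohorts

The generator's realism target is the *marginal* statistics of the two
observed cohorts, not a mechanistic model of child behavior (no
observational study identifies one).  Defaults, per arm:

| quantity | arm A ("Fiji") | arm B ("Indonesia") |
|---|---|---|
| children | 106 | 86 |
| hours/child, mean ± SD (truncated ≥ 0.75) | 3.4 ± 2.1 | 5.1 ± 2.7 |
| observed in both campaigns | 8/106 | 23/86 |
| group rates, contacts/h (food, fomite, own hand, other hand, high-risk) | 18.9, 25.6, 22.6, 3.5, 1.0 | 28.4, 21.1, 19.9, 3.9, 0.4 |
| outdoor-time fraction, mean ± SD | 0.29 ± 0.32 | 0.48 ± 0.315 |
| context prevalence / min/h (feces, animal, water) | 7%/0.2, 60%/2.0, 24%/0.3 | 26%/0.1, 92%/3.3, 38%/0.2 |

Mechanics, all on an integer-millisecond grid:

- **Location**: a semi-Markov renewal process with exponential dwell times
  (IndoorHome mean 15 min, others 5 min) and a rank-1 transition matrix.
  Each child draws a target outdoor fraction from a Beta matched to the
  arm's mean/SD (capped at the feasible variance); the matrix's outdoor
  mass is then the closed-form inverse `p = f·Mi / (f·Mi + (1−f)·Mo)` of
  the stationary time-fraction equation, where Mi/Mo are the
  weight-averaged indoor/outdoor dwell means.
- **Context**: independent Poisson episode processes per context, painted
  over a NoRisk baseline in ascending palette priority so overlaps resolve
  to the higher-risk context.  Each child is first Bernoulli-exposed per
  context (otherwise prevalences would be forced to ~100%); among exposed
  children the episode rate is backed out from the population-mean min/h
  target.
- **Mouthing**: per-group Poisson onsets in observable time, scaled by a
  per-child gamma factor (CV 0.4, matching the observed between-child
  spread) and an extra heavy-tailed gamma factor (shape 0.3) on the
  high-risk group so that only about half of children ever mouth a
  high-risk object.  Object states are uniform within group.  Same-
  millisecond onsets resolve by palette priority.  Contact durations are
  lognormal with median 2 s (σ = 0.8) — unreported in field data and
  cosmetic here, since only counts and channel times feed the metrics —
  truncated at the next onset and at NotInView boundaries.
- **NotInView**: Poisson episodes (2/h, mean 30 s) that override the
  object channel.
- **Demographics**: age group, sex and mobility drawn independently from
  the arm's observed proportions (no age-mobility correlation is modelled;
  demographic factors have no effect on simulated rates, so the
  within-country comparisons are null by construction).
- Rate modifiers conditional on location/context (indoor/outdoor
  multipliers, an eating boost for food) exist but default to 1.0, so the
  configured group rates are exactly the marginal rates.  Consequences:
  the observed indoor > outdoor rate contrast and the large eating-related
  shares are *not* emulated by default — enabling the multipliers
  reproduces them at the cost of inflating the marginal rates.

Ground truth is the realized composed timeline itself (stored per child,
with the generating parameters); with zero coder noise the entire pipeline
— clip splitting, MLATS serialization, parsing, interval reconstruction —
reproduces it exactly, which the test suite asserts byte-for-byte.  Coder
noise perturbs event times with a Gaussian lag, drops object presses with
a miss probability, and misclassifies within (or across) groups.

What passing tests therefore show: the *arithmetic* of the pipeline is
exact, its estimators recover known generating parameters, and the test
procedures hold their nominal size and power under these generating
conditions.  What they cannot show: anything about coder behavior,
camera-induced reactivity, or real children's deviation from
Poisson/renewal structure (overdispersed bursts, diurnal routine,
autocorrelated contexts).

## Numerical choices and problem sizes

- Times are seconds with millisecond resolution; the MLATS serialization
  fixes three decimals and round-trips exactly through IEEE doubles.
- Oracle-equivalence tests run 1000 random integer-second timelines up to
  1 h against the per-second tabulation; end-to-end truth recovery uses
  5-child cohorts; rate recovery uses 200 children at a flat 68 contacts/h
  for 4.1 h; test-calibration checks use 500 null replicates at the
  study's group sizes (106 vs 86) and 200 replicates for the outdoor-time
  power check.  These sizes make the default suite complete in well under
  a minute while keeping Monte-Carlo error far below the tested margins.
- Zero observed time raises; zero *stratum* time yields missing
  conditional rates; degenerate (all-rates-zero) simulator configs produce
  valid contact-free sessions with a warning.

## Known limitations

- Contact counting merges same-object re-taps (see above).
- The simulator's season/campaign labels are metadata only; no seasonal
  behavior model is attempted.
- The location process has identical transition rows (a rank-1 matrix);
  real movement has strong adjacency structure (porch ↔ outside) that a
  full matrix could encode — the config accepts one, but the default does
  not exercise it.
- Pause gaps are excluded from denominators; the alternative (calendar
  time) is not represented because pause logs are not part of the MLATS
  record.
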