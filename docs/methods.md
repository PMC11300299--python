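# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, the
derivation and evaluation of abbreviated-scale clinical decision rules for
neonatal opioid withdrawal syndrome (NOWS) dose-titration algorithms. This
note records the models, conventions and numerical choices, and what the
synthetic experiments do and do not show.

## Instruments

The MOTHER NAS scale (MNAS) scores 19 withdrawal signs on small ordered point
sets (summed range 0–43); the abbreviated sMNAS-9 scores a 9-sign subset of
the same assessment sheet (range 0–19), so one bedside assessment yields both
scores. The shipped definition (`smnas/data/mnas_instrument.yaml`) encodes
items as ordered severity levels with strictly increasing points, plus a list
of recorded-but-unscored elements carried as presence/absence only.

Two encoding decisions matter:

* **Moro reflex is scored 2/3**, the Finnegan convention for hyperactive and
  markedly hyperactive Moro. Published renderings of the item table are
  typographically ambiguous for this row, and the published summed ranges
  (0–43 full, 0–19 short) are the only unambiguous constraint; 2/3 is the
  unique conventional assignment under which the 19 per-item maxima sum to
  exactly 43 while the 9 short items sum to exactly 19. `validate_instrument`
  checks both maxima and both item counts on every load.
* **"Sign absent" is an explicit zero**, distinct from a missing value. A
  record that omits a scored item is invalid rather than silently
  zero-filled: in the emulated workflow every element is assessed every 3–4
  hours, so a gap is a data error worth surfacing.

## Longitudinal metrics

For every scoring time *t* of every infant, on both scales:

* **24-h average** — arithmetic mean over the half-open window (*t* − 24 h,
  *t*], current score included. The window convention is configurable
  (`MetricsConfig.include_current`); including the current score is the
  default because the current assessment should inform the current decision.
* **Sum of 3 consecutive scores** — the current score plus the two before
  it; missing (NaN) until three scores exist. Also switchable to the
  strictly-prior convention.
* **Dose timers** — hours since the last increase-type event ({initiate,
  increase, rescue}: any escalation restarts the stability clock) and since
  the last decrease ({decrease}). Before any dose event both timers run from
  the infant's first score, which defines time 0. The stability flags are
  inclusive (`>= 48 h` since increase, `>= 24 h` since decrease); strict
  comparison is available via `MetricsConfig.inclusive_flags`.

Time is real-valued hours relative to each infant's first score; no calendar
or timezone handling. All metrics are time-translation invariant and
computed independently per infant. Correctness is asserted against naive
brute-force recomputation on randomized series (exact equality, not
tolerance).

## Titration rule engine

A rule set is a prioritized list of guarded rules: a metric condition
(single score / 24-h average / sum-of-3, with a comparator and threshold),
a set of timer and state guards, and a dose action. At each scoring time the
highest-priority rule whose condition and guards all hold fires; at most one
rule fires per step, and the emitted event feeds back into the timers. Doses
are clipped to [0, max]; sum-of-3 rules cannot fire while that sum is
missing (fail-safe toward no dose change); no actions follow
discontinuation.

Shipped rule sets (morphine and buprenorphine, each in a full-scale and a
short-scale variant) share one structure: initiate on a high single score;
rescue on a breakthrough single score during treatment; escalate on a high
sum-of-3 (a larger step at the higher cutoff); wean on a low 24-h average
(or low sum-of-3) after ≥ 48 h dose stability, with weaning steps spaced
≥ 24 h; discontinue once weaning is established, the 24-h average is below
the cutoff, and the dose is at the configured floor. Priorities are
discontinue > decrease > increase > rescue > initiate, reflecting that
weaning decisions dominate once stability criteria are met. Threshold pairs
follow the published full/short pairing, including the comparator-strictness
flip for the low sum-of-3 rule (full `< 18` pairs with short `<= 10`).
**Dose magnitudes (start, steps, rescue, floor, max) are placeholders for
simulation plumbing, not clinical values**; the published figures do not
specify them legibly, and inventing clinical numbers would be worse than
flagging the fields as configuration.

A phenobarbital-adjunct action is representable but ships with no triggering
rule, since "severe despite maximal dosing" is not quantified in the source
material.

## Cutoff derivation

Each full-scale rule condition defines a binary indicator at every metrics
row. Six are used throughout: (i) 24-h average < 8, (ii) ≤ 8, (iii)
sum-of-3 < 18, (iv) ≥ 24, (v) ≥ 28, (vi) single score ≥ 12. The matching
short-scale metric (same form: average↔average, sum↔sum, single↔single) is
the predictor; the optimal cutoff maximizes the Youden index
J = sensitivity + specificity − 1 over the empirical ROC curve.

Conventions:

* Candidates are the distinct observed predictor values plus a
  classify-nothing sentinel; no fixed grid.
* Orientation is inherited from the full-scale comparator (`>=`-type rules
  classify with `predictor >= c`, `<`/`<=`-type with `predictor <= c`), not
  re-estimated.
* Ties break toward the smallest maximizing cutoff (deterministic; favors
  sensitivity for escalation rules).
* Rounding — one decimal for 24-h averages, integers for sums and single
  scores — applies only to the reported cutoff, after optimization.
* Observations are pooled across infants within the training set.

A depth-1 classification tree (Gini impurity, via scikit-learn) is reported
alongside each Youden cutoff as an independent cross-check; the stump's
split is a midpoint between observed values, so the two agree as partitions
rather than as numbers. The Youden optimum is authoritative. The optimizer
is verified against exhaustive candidate search on every instance up to 500
points, and is invariant under strictly monotone predictor transforms.

## Evaluation

Infants are split train/test by independent Bernoulli(0.5) draws from a
seeded generator (sorted ids, so assignment depends only on the id set).
Cutoffs are derived on training rows only; agreement of the short rule with
the full rule is measured on test rows as sensitivity and specificity with
bootstrap percentile 95% intervals. Train/test infant disjointness is
asserted on every evaluation call.

Bootstrap units:

* **observation** (default, mirroring common ROC-bootstrap practice):
  stratified within label class. For binary predictions, resampling the
  n_k exchangeable outcomes of a class with replacement is exactly a
  Binomial(n_k, p̂_k) draw, so the implementation samples binomials
  directly — distributionally identical to index resampling and far faster.
* **infant**: whole infants resampled with replacement (clustered), for the
  autocorrelation-robust alternative; degenerate resamples missing a class
  are redrawn and counted.

Within-infant observations are autocorrelated, so observation-level
intervals are anti-conservative for inference about infants; both units are
offered and neither is claimed to match the original analysis. Percentile
(not normal-approximation) intervals are used because the quantities live in
[0, 1]. Defaults: 2000 resamples, level 0.95, seed required. Coverage of the
observation-unit intervals is verified by simulation (500 replicate
experiments at n = 5000, true sensitivity/specificity 0.9/0.85: observed
coverage ~95%, asserted within 93–97%).

## Synthetic cohorts

`item_level` mode emulates the *structure* of the original data — 373
infants, scoring every 3–4 h, ~170 assessments each — not its score
distributions. Each infant has a latent severity process: a unit-peak
rise–decay mean curve `(t/t_peak)^a · exp(a(1 − t/t_peak))` (peak at
`t_peak_h` = 48 h, late decay rate 1/`decay_h`, default 150 h) scaled
between a baseline (3 full-scale points) and an infant-specific peak
(normal, mean 24, sd 5), plus first-order autoregressive noise (ρ = 0.8 at
the reference 3.5 h step, adjusted per actual gap; sd 3). Treatment
subtracts `treatment_effect` (12 points per dose unit) times the current
dose. Items are emitted by snapping a jittered share of latent severity to
each item's legal ordinal levels, so full and short scores are driven by one
process and correlate above 0.9. With feedback on, the titration engine runs
prospectively on the accumulating scores and its dose events shape the rest
of the trajectory. Everything is reproducible byte-for-byte from the seed.

`planted_mapping` mode is a calibration construct, not a realistic cohort:
full scores are generated directly and the short score is
`floor(full/2) + 1`, the integer map interpolating the two published
calibration pairs (full 8 → short 5, full 12 → short 7). The map is a
construction of this package. Two deliberate choices give it crisp ground
truth:

* **Full scores are quantized to even integers (0–42)** so the floor map is
  exactly affine (short = full/2 + 1) and the windowed metrics inherit exact
  planted boundaries: averages at 8 → 5.0, sums at 18/24/28 → 12/15/17,
  single at 12 → 7. With odd scores the floor smears the sum-of-3 boundary
  by up to 1.5 points and "the planted truth" stops being well defined.
* **Test cohorts compress the decay scale (decay_h = 60)** so a
  ~2000-observation cohort completes the full rise-and-return severity arc
  within its follow-up and every indicator has observations on both sides of
  its boundary; with the item-level default (150 h) a short planted cohort
  never returns to the low-severity regime and the weaning indicators are
  class-degenerate.

Optional noise perturbs each short score by ±1 with probability ε.

What passing these tests shows: the machinery — metrics, optimizer,
split/evaluate chain — recovers known truth under controlled noise. What it
does not show: anything about the real cohort's score distributions,
treatment durations, or the published sensitivities/specificities, which
require the unreleased patient data. The published test-set numbers are
deliberately not reproduction targets; on synthetic cohorts the *derived*
cutoffs differ from the published ones because the synthetic full↔short
relationship differs from the real one — which is exactly why the derivation
procedure, not the numbers, is the reusable object.

One granularity property is worth knowing: on noise-free planted data the
integer-metric rules (sums, single scores) transfer their training cutoff to
the test set with exact 1.0 sensitivity and specificity, but the continuous
24-h-average rules can misclassify a test observation that falls strictly
between the largest training predictor value below the boundary and the
boundary itself. This is inherent to empirical cutoffs on continuous
predictors, shrinks as training size grows, and is asserted at ≥ 0.99 rather
than 1.0.

## Problem sizes

The default test suite and drivers are sized for a laptop-class single CPU:
oracle-equivalence sweeps use 1000 randomized series and 60 exhaustive
Youden instances up to n = 500; recovery uses a ~2000-observation planted
cohort; coverage uses 500 replicates of n = 5000 (fast via the binomial
identity); the full simulated cohort (373 infants, ~64k scores, prospective
engine feedback) generates in ~15 s. The whole suite runs in well under a
minute.

## Known limitations

* Dose magnitudes are placeholders; no pharmacokinetics, no mg/kg weight
  adjustment, no claim of clinical validity.
* No imputation of missed assessments and no calendar-time handling.
* The item-emission model is a convenience (thresholded shared latent
  process with independent jitter), not a fitted measurement model.
* The original analysis's conventions on two points — whether the current
  score enters the 24-h average and the sum-of-3, and which average
  indicator (strict vs non-strict) gates each weaning step — are not stated
  in the source; both are configuration here, with the defaults above.
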