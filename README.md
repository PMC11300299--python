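# smnas

Abbreviated-scale clinical decision rules for neonatal opioid withdrawal
syndrome (NOWS) dose titration: derivation, execution and evaluation, with a
synthetic cohort generator so the whole pipeline is testable without patient
data.

## The problem

Infants with NOWS are assessed every 3–4 hours with the MOTHER NAS scale
(MNAS), a 19-item Finnegan-type instrument (summed score 0–43). Morphine and
buprenorphine titration algorithms act on longitudinal functions of these
scores — a single high score initiates treatment or triggers a rescue dose,
a high sum of 3 consecutive scores escalates the dose, a low 24-hour average
(after ≥ 48 h dose stability) weans it. Scoring 19 items every few hours is
a real burden; the abbreviated sMNAS-9 scores a 9-item subset of the same
sheet (range 0–19). The question this package operationalizes: **which
sMNAS-9 cutoffs make the short-scale decision rules reproduce the full-scale
rules?**

For each full-scale rule indicator (e.g. *24-h average MNAS < 8*, *sum of 3
consecutive ≥ 24*, *single score ≥ 12*) the matching short-scale metric is
treated as a predictor and the optimal cutoff c maximizes the Youden index
over the empirical ROC curve,

    J(c) = sensitivity(c) + specificity(c) − 1,

on a training half of the cohort (infant-level Bernoulli(0.5) split), with a
depth-1 CART split as a cross-check. The derived short-scale rules are then
evaluated on the held-out infants by sensitivity/specificity with bootstrap
percentile 95% CIs, and the short-scale titration algorithm can be run head
to head against the full-scale one by a deterministic rule engine.

## Layout

- `src/smnas/` — the library: `instrument` (MNAS/sMNAS-9 encoding and
  scoring), `metrics` (24-h averages, sums of 3, dose timers),
  `engine` (guarded-rule titration algorithms; four shipped rule sets),
  `cutoffs` (Youden optimizer, ROC, CART stump), `evaluation`
  (split/confusion/bootstrap), `simulate` (synthetic cohorts),
  `pipeline` (recalibrating a rule set from derived cutoffs).
- `analysis/` — numbered drivers for the end-to-end study, each writing
  under `results/`.
- `docs/methods.md` — models, conventions, numerical choices, limitations.

## Worked example

The full chain on a synthetic cohort emulating the published data structure
(373 infants, ~64k scores, the titration engine running prospectively in
feedback with severity):

```
$ python analysis/01_simulate_cohort.py --seed 0
cohort: 373 infants, 64088 scores, 8130 dose events
treated: 369 initiated, 369 weaned off

$ python analysis/02_compute_metrics.py
metrics: 64088 rows from 373 infants; sum-of-3 defined on 98.8% of rows

$ python analysis/03_derive_cutoffs.py --seed 0
split: 171 train / 202 test infants (29394 training rows)
  indicator i: short avg24 <= 3.1 (J = 0.942, stump 3.9375)
  indicator ii: short avg24 <= 3.1 (J = 0.940, stump 4.0625)
  indicator iii: short sum3 <= 7 (J = 0.921, stump 8.5)
  indicator iv: short sum3 >= 10 (J = 0.935, stump 12.5)
  indicator v: short sum3 >= 10 (J = 0.931, stump 13.5)
  indicator vi: short single_score >= 5 (J = 0.900, stump 5.5)

$ python analysis/04_evaluate_rules.py --seed 0
  indicator i: sens 95.9% (95.7%-96.1%), spec 98.4% (97.9%-98.9%)
  indicator ii: sens 95.6% (95.4%-95.8%), spec 98.7% (98.2%-99.1%)
  indicator iii: sens 95.5% (95.2%-95.7%), spec 96.7% (96.1%-97.3%)
  indicator iv: sens 97.6% (96.9%-98.2%), spec 95.8% (95.5%-96.0%)
  indicator v: sens 99.1% (98.6%-99.5%), spec 93.9% (93.7%-94.2%)
  indicator vi: sens 95.3% (93.9%-96.6%), spec 95.8% (95.6%-96.0%)
```

Reading this: on the training infants, the cutoff that best reproduces each
full-scale rule is found (e.g. a short-scale sum of 3 ≥ 10 best mirrors the
full-scale *sum of 3 ≥ 24* escalation rule on this cohort, with Youden index
0.935); on the held-out infants, each short rule then agrees with its
full-scale counterpart with roughly 94–99% sensitivity and specificity. The
derived cutoffs differ from the published ones because the synthetic
full↔short score relationship differs from the real cohort's — the
procedure, not the cutoff values, is the transferable object.

The fifth driver runs the algorithms head to head on a common cohort:

```
$ python analysis/05_algorithm_concordance.py --seed 0
published: 1/56 identical traces, median initiation diff 0 h, median action-count diff 6
recalibrated: 2/56 identical traces, median initiation diff 0 h, median action-count diff 2
```

Exact whole-episode identity is stringent (one divergent decision cascades
through the dose timers); the informative result is that both short-scale
algorithms initiate treatment at the same time as the full-scale one for the
median infant, and recalibrating the cutoffs to the cohort (rather than
using cutoffs calibrated elsewhere) cuts the episode-length divergence from
6 actions to 2.

`01` and `02` write large per-observation CSVs (`results/cohort/scores.csv`,
`results/metrics.csv`) that are regenerated on demand and not tracked.

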