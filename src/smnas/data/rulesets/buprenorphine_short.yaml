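# Buprenorphine titration algorithm driven by short-scale (sMNAS-9) metrics
# with the published short-scale cutoff pairs.  Dose magnitudes are
# PLACEHOLDERS, not clinical guidance.
drug: buprenorphine
scale: short
dose_units: "mg/day equivalent (placeholder, non-clinical)"
start_dose: 0.05
max_dose: 0.2
min_dose: 0.015
rules:
  - name: discontinue
    action: discontinue
    priority: 70
    condition: {metric: avg24, comparator: "<", threshold: 4.6}
    timer_guards: [treating, had_first_decrease, 24h_since_decrease]
    dose_at_most: 0.025
  - name: wean
    action: decrease
    priority: 60
    condition: {metric: avg24, comparator: "<=", threshold: 4.6}
    timer_guards: [treating, 48h_since_increase, 24h_since_decrease]
    dose_delta: -0.015
  - name: wean_sum3
    action: decrease
    priority: 55
    condition: {metric: sum3, comparator: "<=", threshold: 10}
    timer_guards: [treating, 48h_since_increase, 24h_since_decrease]
    dose_delta: -0.015
  - name: escalate_fast
    action: increase
    priority: 50
    condition: {metric: sum3, comparator: ">=", threshold: 16}
    timer_guards: [treating]
    dose_delta: 0.03
  - name: escalate
    action: increase
    priority: 40
    condition: {metric: sum3, comparator: ">=", threshold: 14}
    timer_guards: [treating]
    dose_delta: 0.015
  - name: rescue
    action: rescue
    priority: 30
    condition: {metric: single_score, comparator: ">=", threshold: 7}
    timer_guards: [treating]
    dose_delta: 0.015
  - name: initiate
    action: initiate
    priority: 10
    condition: {metric: single_score, comparator: ">=", threshold: 7}
    timer_guards: [not_yet_treating]
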