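# Morphine titration algorithm driven by short-scale (sMNAS-9) longitudinal
# metrics, using the published short-scale cutoff pairs (24-h average 4.6,
# sum-of-3 low 10 with a non-strict comparator, escalation 14/16, single 7).
# Dose magnitudes are PLACEHOLDERS, not clinical guidance.
drug: morphine
scale: short
dose_units: "mg/day equivalent (placeholder, non-clinical)"
start_dose: 0.4
max_dose: 1.2
min_dose: 0.1
rules:
  - name: discontinue
    action: discontinue
    priority: 70
    condition: {metric: avg24, comparator: "<", threshold: 4.6}
    timer_guards: [treating, had_first_decrease, 24h_since_decrease]
    dose_at_most: 0.15
  - name: wean
    action: decrease
    priority: 60
    condition: {metric: avg24, comparator: "<=", threshold: 4.6}
    timer_guards: [treating, 48h_since_increase, 24h_since_decrease]
    dose_delta: -0.1
  - name: wean_sum3
    action: decrease
    priority: 55
    condition: {metric: sum3, comparator: "<=", threshold: 10}
    timer_guards: [treating, 48h_since_increase, 24h_since_decrease]
    dose_delta: -0.1
  - name: escalate_fast
    action: increase
    priority: 50
    condition: {metric: sum3, comparator: ">=", threshold: 16}
    timer_guards: [treating]
    dose_delta: 0.2
  - name: escalate
    action: increase
    priority: 40
    condition: {metric: sum3, comparator: ">=", threshold: 14}
    timer_guards: [treating]
    dose_delta: 0.1
  - name: rescue
    action: rescue
    priority: 30
    condition: {metric: single_score, comparator: ">=", threshold: 7}
    timer_guards: [treating]
    dose_delta: 0.1
  - name: initiate
    action: initiate
    priority: 10
    condition: {metric: single_score, comparator: ">=", threshold: 7}
    timer_guards: [not_yet_treating]
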