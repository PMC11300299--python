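# The MOTHER NAS scale (MNAS, 19 scored items, summed range 0-43) and the
# abbreviated sMNAS-9 (the 9 items flagged in_short, summed range 0-19).
# Severity descriptions are carried verbatim-ish for documentation but are
# never matched on; the stable identifiers are the snake_case item names.
#
# Moro reflex is scored 2/3 following the Finnegan convention for
# hyperactive / markedly hyperactive Moro; this reconciles the per-item maxima
# with the instrument's published summed range of 0-43.
name: mnas
items:
  - name: crying
    in_short: true
    levels:
      - {description: "Excessive high pitched", points: 2}
      - {description: "Continuous high pitched", points: 3}
  - name: sleeps
    in_short: true
    levels:
      - {description: "Sleeps <3 h after feeding", points: 1}
      - {description: "Sleeps <2 h after feeding", points: 2}
      - {description: "Sleeps <1 h after feeding", points: 3}
  - name: moro_reflex
    in_short: false
    levels:
      - {description: "Hyperactive", points: 2}
      - {description: "Markedly hyperactive", points: 3}
  - name: tremors_disturbed
    in_short: false
    levels:
      - {description: "Hands or feet only, up to 3 s", points: 1}
      - {description: "Arms or legs, over 3 s", points: 2}
  - name: tremors_undisturbed
    in_short: true
    levels:
      - {description: "Hands or feet only, up to 3 s", points: 1}
      - {description: "Arms or legs, over 3 s", points: 2}
  - name: increased_muscle_tone
    in_short: true
    levels:
      - {description: "Difficult but possible to straighten arm, head lag present", points: 1}
      - {description: "Unable to straighten arm, head lag absent", points: 2}
  - name: fever
    in_short: true
    levels:
      - {description: ">37.3 C (99.2 F)", points: 1}
  - name: tachypnea
    in_short: true
    levels:
      - {description: "Respiratory rate >60/min", points: 2}
  - name: poor_feeding
    in_short: true
    levels:
      - {description: "Takes >20 min, uncoordinated, small volume, frequent stops to breathe", points: 2}
  - name: vomiting
    in_short: true
    levels:
      - {description: "Vomits whole feeds, or at least x2/feed when not burping", points: 2}
  - name: loose_stools
    in_short: true
    levels:
      - {description: "Diaper is half liquid/half solid with or without water ring", points: 2}
  - name: excoriation
    in_short: false
    levels:
      - {description: "Skin is red but intact or healing, no longer broken", points: 1}
      - {description: "Skin not intact", points: 2}
  - name: generalized_seizure
    in_short: false
    levels:
      - {description: "Staring, rapid involuntary eye movements, chewing, back arching, fist clenching, tonic-clonic movements", points: 8}
  - name: frequent_yawning
    in_short: false
    levels:
      - {description: "4 or more successive times", points: 1}
  - name: sweating
    in_short: false
    levels:
      - {description: "Wetness on forehead or upper lip", points: 1}
  - name: nasal_stuffiness
    in_short: false
    levels:
      - {description: "Any nasal noise", points: 1}
  - name: sneezing
    in_short: false
    levels:
      - {description: "4 or more successive times", points: 1}
  - name: failure_to_thrive
    in_short: false
    levels:
      - {description: "Current weight >=10% below birth weight", points: 2}
  - name: excessive_irritability
    in_short: false
    levels:
      - {description: "Consoling calms infant in 5 min or less", points: 1}
      - {description: "Consoling calms infant in 6-15 min", points: 2}
      - {description: "Consoling takes >15 min or is unsuccessful", points: 3}
unscored_elements:
  - myoclonic_jerks
  - mottling
  - convulsions
  - fever_38_4
  - retractions
  - nasal_flaring
  - excessive_sucking
  - projectile_vomiting
  - watery_stools
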