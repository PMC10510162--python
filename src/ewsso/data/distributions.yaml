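# Generative parameters for the synthetic critical-care vitals datasets.
#
# Continuous/integer vitals are drawn from a normal distribution whose median
# and IQR are configured directly (sigma = IQR / (2 * 0.67448975...)) and
# truncated to the extreme range by rejection.  The medians/IQRs below are
# structural placeholders in the spirit of an emergency-department cohort —
# calibrate to a cohort of interest if realism beyond score coverage matters.
# Extreme ranges are wide enough that every scoring band of every rubric is
# reachable.
n_patients: 1000
missing_rate: 0.05
fahrenheit_fraction: 0.5   # per-patient probability a temperature is recorded in degF

vitals:
  - name: respiratory_rate
    unit: breaths/min
    value_kind: integer
    median: 18
    q1: 16
    q3: 20
    range_min: 4
    range_max: 45
    precision: 0
  - name: oxygen_saturation
    unit: "%"
    value_kind: integer
    median: 97
    q1: 95
    q3: 98
    range_min: 70
    range_max: 100
    precision: 0
  - name: supplemental_oxygen
    unit: null
    value_kind: categorical
    category_probs: {"yes": 0.2, "no": 0.8}
  - name: body_temperature
    unit: degC
    value_kind: continuous
    median: 36.9
    q1: 36.5
    q3: 37.3
    range_min: 33.0
    range_max: 42.0
    precision: 1
  - name: systolic_blood_pressure
    unit: mmHg
    value_kind: integer
    median: 135
    q1: 120
    q3: 152
    range_min: 50
    range_max: 250
    precision: 0
  - name: heart_rate
    unit: beats/min
    value_kind: integer
    median: 84
    q1: 72
    q3: 98
    range_min: 25
    range_max: 190
    precision: 0
  - name: avpu
    unit: null
    value_kind: categorical
    category_probs: {A: 0.85, V: 0.08, P: 0.04, U: 0.03}
  - name: urine_output
    unit: mL/kg/h
    value_kind: continuous
    median: 1.2
    q1: 0.8
    q3: 1.6
    range_min: 0.0
    range_max: 4.0
    precision: 1

# Clinical/demographic columns present only in the distractor dataset; none
# of them is an input to NEWS, the six-item MEWS, or qSOFA.
distractors:
  - name: age
    unit: years
    value_kind: integer
    median: 58
    q1: 42
    q3: 71
    range_min: 18
    range_max: 100
    precision: 0
  - name: sex
    unit: null
    value_kind: categorical
    category_probs: {female: 0.5, male: 0.5}
  - name: weight
    unit: kg
    value_kind: continuous
    median: 80.0
    q1: 68.0
    q3: 95.0
    range_min: 35.0
    range_max: 180.0
    precision: 1
  - name: diastolic_blood_pressure
    unit: mmHg
    value_kind: integer
    median: 78
    q1: 68
    q3: 88
    range_min: 30
    range_max: 150
    precision: 0
  - name: admission_ward
    unit: null
    value_kind: categorical
    category_probs: {emergency: 0.4, medical: 0.3, surgical: 0.2, icu: 0.1}
  - name: pain_score
    unit: null
    value_kind: integer
    median: 3
    q1: 1
    q3: 6
    range_min: 0
    range_max: 10
    precision: 0
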