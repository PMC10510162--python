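# Six-item Modified Early Warning Score rubric (respiratory rate, heart
# rate, systolic pressure, temperature, AVPU, urine output).
score: MEWS6
label: six-item modified early warning score
parameters:
  - datum: respiratory rate measurement datum
    unit: breaths/min
    precision: 0
    domain: [4, 45]
    bands:
      - [null, 8, 2]
      - [9, 14, 0]
      - [15, 20, 1]
      - [21, 29, 2]
      - [30, null, 3]
  - datum: heart rate measurement datum
    unit: beats/min
    precision: 0
    domain: [25, 190]
    bands:
      - [null, 40, 2]
      - [41, 50, 1]
      - [51, 100, 0]
      - [101, 110, 1]
      - [111, 129, 2]
      - [130, null, 3]
  - datum: systolic blood pressure measurement datum
    unit: mmHg
    precision: 0
    domain: [50, 250]
    bands:
      - [null, 70, 3]
      - [71, 80, 2]
      - [81, 100, 1]
      - [101, 199, 0]
      - [200, null, 2]
  - datum: body temperature measurement datum
    unit: degC
    precision: 1
    domain: [33.0, 42.0]
    bands:
      - [null, 34.9, 2]
      - [35.0, 38.4, 0]
      - [38.5, null, 2]
  - datum: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
    categories: {A: 0, V: 1, P: 2, U: 3}
  - datum: urine output measurement datum
    unit: mL/kg/h
    precision: 1
    domain: [0.0, 4.0]
    bands:
      - [0.0, 0.0, 3]
      - [0.1, 0.4, 2]
      - [0.5, 0.9, 1]
      - [1.0, null, 0]
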