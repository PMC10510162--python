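# National Early Warning Score rubric (standard published chart).
# Bands are [lower, upper, points]; null means unbounded on that side.
# Boundaries are interpreted as closed intervals on the recording-precision
# grid (precision = decimal places); `domain` is the plausible value range
# used by the load-time coverage/exclusivity validation.
score: NEWS
label: national early warning score
parameters:
  - datum: respiratory rate measurement datum
    unit: breaths/min
    precision: 0
    domain: [4, 45]
    bands:
      - [null, 8, 3]
      - [9, 11, 1]
      - [12, 20, 0]
      - [21, 24, 2]
      - [25, null, 3]
  - datum: oxygen saturation measurement datum
    unit: "%"
    precision: 0
    domain: [70, 100]
    bands:
      - [null, 91, 3]
      - [92, 93, 2]
      - [94, 95, 1]
      - [96, null, 0]
  - datum: supplemental oxygen use measurement datum
    categories: {"yes": 2, "no": 0}
  - datum: body temperature measurement datum
    unit: degC
    precision: 1
    domain: [33.0, 42.0]
    bands:
      - [null, 35.0, 3]
      - [35.1, 36.0, 1]
      - [36.1, 38.0, 0]
      - [38.1, 39.0, 1]
      - [39.1, null, 2]
  - datum: systolic blood pressure measurement datum
    unit: mmHg
    precision: 0
    domain: [50, 250]
    bands:
      - [null, 90, 3]
      - [91, 100, 2]
      - [101, 110, 1]
      - [111, 219, 0]
      - [220, null, 3]
  - datum: heart rate measurement datum
    unit: beats/min
    precision: 0
    domain: [25, 190]
    bands:
      - [null, 40, 3]
      - [41, 50, 1]
      - [51, 90, 0]
      - [91, 110, 1]
      - [111, 130, 2]
      - [131, null, 3]
  - datum: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
    categories: {A: 0, V: 3, P: 3, U: 3}
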