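# Quick Sequential Organ Failure Assessment rubric (Sepsis-3 criteria):
# one point each for respiratory rate >= 22, systolic pressure <= 100 mmHg,
# and altered mentation (GCS < 15).  When only an AVPU assessment exists,
# GCS is derived through the published AVPU-to-GCS mapping first.
score: qSOFA
label: quick sequential organ failure assessment
parameters:
  - datum: Glasgow coma scale measurement datum
    precision: 0
    domain: [3, 15]
    derive_from:
      datum: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
      conversion: avpu_to_gcs
    bands:
      - [3, 14, 1]
      - [15, 15, 0]
  - datum: respiratory rate measurement datum
    unit: breaths/min
    precision: 0
    domain: [4, 45]
    bands:
      - [null, 21, 0]
      - [22, null, 1]
  - datum: systolic blood pressure measurement datum
    unit: mmHg
    precision: 0
    domain: [50, 250]
    bands:
      - [null, 100, 1]
      - [101, null, 0]
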