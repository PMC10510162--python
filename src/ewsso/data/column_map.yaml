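# Dataset column -> ontology class label used during triplification.
# Columns under `distractors` are tagged in a separate, non-EWSSO namespace
# so that differentiation between score-relevant and irrelevant features is
# exercised at query time, not by dropping columns at load time.
# `unit_for` columns carry the unit literal of another column's measurement.
vitals:
  respiratory_rate: respiratory rate measurement datum
  oxygen_saturation: oxygen saturation measurement datum
  supplemental_oxygen: supplemental oxygen use measurement datum
  body_temperature: body temperature measurement datum
  systolic_blood_pressure: systolic blood pressure measurement datum
  heart_rate: heart rate measurement datum
  avpu: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
  gcs: Glasgow coma scale measurement datum
  urine_output: urine output measurement datum
unit_columns:
  body_temperature_unit: body_temperature
distractors:
  - age
  - sex
  - weight
  - diastolic_blood_pressure
  - admission_ward
  - pain_score
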