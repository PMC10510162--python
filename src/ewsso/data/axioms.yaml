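# Axiom table for the EWSSO: subject / property / object, all by class label.
# Emitted as OWL existential restrictions (someValuesFrom) on the subject
# class. Summation processes consume the vital-function measurement data and
# produce the aggregate score; scoring processes produce the per-parameter
# measurement datum scores.
axioms:
  - {subject: early warning score, property: is about, object: clinical deterioration}

  # ---- national early warning score (seven inputs) ----------------------
  - {subject: national early warning score summation process, property: has_specified_input, object: respiratory rate measurement datum}
  - {subject: national early warning score summation process, property: has_specified_input, object: systolic blood pressure measurement datum}
  - {subject: national early warning score summation process, property: has_specified_input, object: heart rate measurement datum}
  - {subject: national early warning score summation process, property: has_specified_input, object: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"}
  - {subject: national early warning score summation process, property: has_specified_input, object: body temperature measurement datum}
  - {subject: national early warning score summation process, property: has_specified_input, object: oxygen saturation measurement datum}
  - {subject: national early warning score summation process, property: has_specified_input, object: supplemental oxygen use measurement datum}
  - {subject: national early warning score summation process, property: has_specified_output, object: national early warning score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: respiratory rate measurement datum score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: systolic blood pressure measurement datum score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: heart rate measurement datum score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum score"}
  - {subject: national early warning score scoring process, property: has_specified_output, object: body temperature measurement datum score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: oxygen saturation measurement datum score}
  - {subject: national early warning score scoring process, property: has_specified_output, object: supplemental oxygen use measurement datum score}

  # ---- six-item modified early warning score (six inputs) ---------------
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: respiratory rate measurement datum}
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: systolic blood pressure measurement datum}
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: urine output measurement datum}
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: heart rate measurement datum}
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"}
  - {subject: six-item modified early warning score summation process, property: has_specified_input, object: body temperature measurement datum}
  - {subject: six-item modified early warning score summation process, property: has_specified_output, object: six-item modified early warning score}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: respiratory rate measurement datum score}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: systolic blood pressure measurement datum score}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: urine output measurement datum score}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: heart rate measurement datum score}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum score"}
  - {subject: six-item modified early warning score scoring process, property: has_specified_output, object: body temperature measurement datum score}

  # ---- quick sequential organ failure assessment (three inputs) ---------
  - {subject: quick sequential organ failure assessment score summation process, property: has_specified_input, object: Glasgow coma scale measurement datum}
  - {subject: quick sequential organ failure assessment score summation process, property: has_specified_input, object: respiratory rate measurement datum}
  - {subject: quick sequential organ failure assessment score summation process, property: has_specified_input, object: systolic blood pressure measurement datum}
  - {subject: quick sequential organ failure assessment score summation process, property: has_specified_output, object: quick sequential organ failure assessment}
  - {subject: quick sequential organ failure assessment scoring process, property: has_specified_output, object: Glasgow coma scale measurement datum score}
  - {subject: quick sequential organ failure assessment scoring process, property: has_specified_output, object: respiratory rate measurement datum score}
  - {subject: quick sequential organ failure assessment scoring process, property: has_specified_output, object: systolic blood pressure measurement datum score}
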