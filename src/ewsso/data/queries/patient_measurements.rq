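# All measurement data for one patient (bind ?pid to the patient identifier).
SELECT ?p ?cls ?value ?unit WHERE {
    ?p vocab:patientId ?pid ;
       vocab:hasMeasurement ?m .
    ?m a ?cls ;
       vocab:hasValue ?value .
    OPTIONAL { ?m vocab:hasUnit ?unit }
}
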