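# Measurement data for one patient restricted to a score's required classes.
# {values} is replaced with the space-separated IRIs of the specified-input
# set; VALUES stays after the patterns so the pre-bound ?pid keeps
# evaluation on the per-patient index.
SELECT ?p ?cls ?value ?unit WHERE {
    ?p vocab:patientId ?pid ;
       vocab:hasMeasurement ?m .
    ?m a ?cls ;
       vocab:hasValue ?value .
    VALUES ?cls { {values} }
    OPTIONAL { ?m vocab:hasUnit ?unit }
}
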