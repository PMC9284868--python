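iri_a	iri_b
http://www.orpha.net/ORDO/Orphanet_C001	http://snomed.info/id/404684003
http://www.orpha.net/ORDO/Orphanet_C010	http://snomed.info/id/105590001
http://www.orpha.net/ORDO/Orphanet_C009	http://snomed.info/id/308916002
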