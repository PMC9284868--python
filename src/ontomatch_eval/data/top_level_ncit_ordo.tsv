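iri_a	iri_b
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C7057	http://www.orpha.net/ORDO/Orphanet_C001
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C26548	http://www.orpha.net/ORDO/Orphanet_C010
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20181	http://www.orpha.net/ORDO/Orphanet_C009
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20181	http://www.orpha.net/ORDO/Orphanet_C005
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20189	http://www.orpha.net/ORDO/Orphanet_C023
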