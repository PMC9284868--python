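iri_a	iri_b
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C12219	http://snomed.info/id/123037004
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C7057	http://snomed.info/id/404684003
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20189	http://snomed.info/id/362981000
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C12219	http://snomed.info/id/105590001
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C43431	http://snomed.info/id/71388002
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C14250	http://snomed.info/id/410607006
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C1908	http://snomed.info/id/105590001
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C1908	http://snomed.info/id/373873005
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C97325	http://snomed.info/id/260787004
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20189	http://snomed.info/id/363787002
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20181	http://snomed.info/id/308916002
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20181	http://snomed.info/id/48176007
http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#C20181	http://snomed.info/id/363787002
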