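category,icd10_prefixes,drug_classes
nausea_vomiting,R11,antiemetic
neutropenia_leukopenia,D70,g_csf
febrile_neutropenia,D70,g_csf;antibiotic
anemia,D50;D51;D52;D53;D55;D56;D57;D58;D59;D60;D61;D62;D63;D64,anemia_rx
diarrhea,A09;K52;K591,antidiarrheal
ild,J84,corticosteroid
peripheral_neuropathy,G62,neuropathy_rx
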