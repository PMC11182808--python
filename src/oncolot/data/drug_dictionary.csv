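code,name,classes
D001,doxorubicin,anthracycline
D002,epirubicin,anthracycline
D010,paclitaxel,taxane
D011,docetaxel,taxane
D012,nab-paclitaxel,taxane
D020,atezolizumab,ici
D021,pembrolizumab,ici
D030,capecitabine,bc_other
D031,tegafur-gimeracil-oteracil,bc_other
D032,tegafur-uracil,bc_other
D033,eribulin,bc_other
D034,gemcitabine,bc_other
D035,carboplatin,bc_other
D036,vinorelbine,bc_other
D037,irinotecan,bc_other
D038,cyclophosphamide,bc_other
D039,fluorouracil,bc_other
D040,methotrexate,bc_other
D041,bevacizumab,bc_other
H001,tamoxifen,hormonal
H002,letrozole,hormonal
H003,fulvestrant,hormonal
H004,anastrozole,hormonal
T001,trastuzumab,anti_her2
T002,pertuzumab,anti_her2
T003,lapatinib,anti_her2
A001,granisetron,ae_treatment:antiemetic
A002,aprepitant,ae_treatment:antiemetic
A003,filgrastim,ae_treatment:g_csf
A004,pegfilgrastim,ae_treatment:g_csf
A005,cefepime,ae_treatment:antibiotic
A006,epoetin,ae_treatment:anemia_rx
A007,loperamide,ae_treatment:antidiarrheal
A008,prednisolone,ae_treatment:corticosteroid
A009,pregabalin,ae_treatment:neuropathy_rx
A010,duloxetine,ae_treatment:neuropathy_rx
N001,amlodipine,non_bc
N002,metformin,non_bc
N003,rosuvastatin,non_bc
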