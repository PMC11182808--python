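name,components,category
Capecitabine,capecitabine,other
S-1 (Tegafur-Gimeracil-Oteracil),tegafur-gimeracil-oteracil,other
Tegafur-Uracil,tegafur-uracil,other
Doxorubicin/Cyclophosphamide,doxorubicin;cyclophosphamide,anthracycline_containing
Epirubicin/Cyclophosphamide,epirubicin;cyclophosphamide,anthracycline_containing
Epirubicin/Fluorouracil/Cyclophosphamide,epirubicin;fluorouracil;cyclophosphamide,anthracycline_containing
Docetaxel/Cyclophosphamide,docetaxel;cyclophosphamide,taxane_containing
Paclitaxel,paclitaxel,taxane_containing
Docetaxel,docetaxel,taxane_containing
Nab-Paclitaxel,nab-paclitaxel,taxane_containing
Atezolizumab/Nab-Paclitaxel,atezolizumab;nab-paclitaxel,taxane_containing
Pembrolizumab/Paclitaxel,pembrolizumab;paclitaxel,taxane_containing
Pembrolizumab/Nab-Paclitaxel,pembrolizumab;nab-paclitaxel,taxane_containing
Bevacizumab/Paclitaxel,bevacizumab;paclitaxel,taxane_containing
Pembrolizumab/Gemcitabine/Carboplatin,pembrolizumab;gemcitabine;carboplatin,taxane_containing
Cyclophosphamide/Methotrexate/Fluorouracil,cyclophosphamide;methotrexate;fluorouracil,other
Eribulin,eribulin,other
Vinorelbine,vinorelbine,other
Gemcitabine,gemcitabine,other
Gemcitabine/Carboplatin,gemcitabine;carboplatin,other
Irinotecan,irinotecan,other
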