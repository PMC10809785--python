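protocol,arm,agent,cumulative_dose,units
ALL-2020,standard_risk,vincristine,24,mg/m2
ALL-2020,standard_risk,doxorubicin,120,mg/m2
ALL-2020,standard_risk,methotrexate,20000,mg/m2
ALL-2020,standard_risk,cyclophosphamide,2000,mg/m2
ALL-2020,standard_risk,asparaginase,90000,mg/m2
ALL-2020,standard_risk,mercaptopurine,25000,mg/m2
ALL-2020,high_risk,vincristine,30,mg/m2
ALL-2020,high_risk,doxorubicin,240,mg/m2
ALL-2020,high_risk,methotrexate,33000,mg/m2
ALL-2020,high_risk,cyclophosphamide,4000,mg/m2
ALL-2020,high_risk,cytarabine,12000,mg/m2
AML-2019,induction,daunorubicin,180,mg/m2
AML-2019,induction,cytarabine,24000,mg/m2
AML-2019,induction,etoposide,1500,mg/m2
AML-2019,induction,mitoxantrone,30,mg/m2
MB-SIOP,standard,cisplatin,210,mg/m2
MB-SIOP,standard,lomustine,300,mg/m2
MB-SIOP,standard,vincristine,18,mg/m2
LGG-VC,standard,vincristine,27,mg/m2
LGG-VC,standard,carboplatin,4950,mg/m2
HL-EuroNet,OEPA,doxorubicin,160,mg/m2
HL-EuroNet,OEPA,etoposide,2500,mg/m2
HL-EuroNet,OEPA,procarbazine,3000,mg/m2
HL-EuroNet,OEPA_COPDAC,doxorubicin,160,mg/m2
HL-EuroNet,OEPA_COPDAC,cyclophosphamide,4000,mg/m2
HL-EuroNet,OEPA_COPDAC,dactinomycin,6,mg/m2
NHL-LMB,group_B,doxorubicin,120,mg/m2
NHL-LMB,group_B,cyclophosphamide,3300,mg/m2
NHL-LMB,group_B,methotrexate,24000,mg/m2
NHL-LMB,group_B,rituximab,1870,mg/m2
EWS-2008,VIDE,vincristine,12,mg/m2
EWS-2008,VIDE,ifosfamide,54000,mg/m2
EWS-2008,VIDE,doxorubicin,360,mg/m2
EWS-2008,VIDE,etoposide,4500,mg/m2
OS-2016,MAP,methotrexate,144000,mg/m2
OS-2016,MAP,doxorubicin,450,mg/m2
OS-2016,MAP,cisplatin,480,mg/m2
RMS-EpSSG,IVA,ifosfamide,54000,mg/m2
RMS-EpSSG,IVA,vincristine,22.5,mg/m2
RMS-EpSSG,IVA,dactinomycin,13.5,mg/m2
WT-SIOP,AV,vincristine,15,mg/m2
WT-SIOP,AV,dactinomycin,1.8,mg/m2
WT-SIOP,AVD,vincristine,15,mg/m2
WT-SIOP,AVD,dactinomycin,1.8,mg/m2
WT-SIOP,AVD,doxorubicin,250,mg/m2
NB-HR,induction,cisplatin,320,mg/m2
NB-HR,induction,etoposide,1275,mg/m2
NB-HR,induction,cyclophosphamide,6300,mg/m2
NB-HR,induction,vincristine,9,mg/m2
NB-HR,consolidation,busulfan,19.2,mg/kg
NB-HR,consolidation,melphalan,140,mg/m2
GCT-PEI,standard,cisplatin,400,mg/m2
GCT-PEI,standard,etoposide,1500,mg/m2
GCT-PEI,standard,ifosfamide,30000,mg/m2
HSCT-COND,bu_mel,busulfan,19.2,mg/kg
HSCT-COND,bu_mel,melphalan,140,mg/m2
HSCT-COND,tbi_cy,cyclophosphamide,120,mg/kg
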