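case_id,diagnosis,sex,age_years,brain_weight_g,pmi_h,mr,epilepsy,regression,hemisphere
B-6115,autism,F,17,1158,25,no,no,no,left
B-6403,autism,M,7,1610,25,no,yes,yes,right
UMB-1627,autism,F,5,1390,13.3,no,no,no,right
IBR-93-01,autism,M,23,1610,14,no,yes,no,right
B-6276,autism,M,56,1570,3.4,moderate,no,no,right
B-6212,autism,M,36,1480,24,severe,no,yes,right
UMB-1638,autism,F,21,1108,50,mild,yes,yes,right
B-5666,autism,M,8,1570,22.2,no,no,no,right
UMB-1843,control,F,15,1250,9,no,no,,right
UMB-1846,control,F,20,1340,9,no,no,,right
UMB-4898,control,M,7,1240,12,no,no,,right
B-6736,control,F,4,1530,17.0,no,no,,right
UMB-1646,control,M,23,1520,6,no,no,,right
BTB-3983,control,M,52,1430,12.5,no,no,,right
UMB-1576,control,M,32,,24,no,no,,right
IBR-252-02,control,M,51,1450,18,no,no,,left
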