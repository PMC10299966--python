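cause,group
sepsis,group1
pneumonia,group1
tetanus,group1
diarrhoea,group1
prematurity,group2
intrauterine_growth_restriction,group2
congenital_anomalies,group2
intrapartum,group3
birth_asphyxia,group3
birth_trauma,group3
other,other
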