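cause,group
infection,group1
syphilis,group1
malaria,group1
fetal_growth_restriction,group2
maternal_conditions,group2
congenital_anomalies,group2
intrapartum,group3
placental_abruption,group3
other,other
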