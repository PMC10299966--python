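cause,group
abortion_complications,group1
sepsis,group1
other_infections,group1
indirect_causes,group2
pre_existing_conditions,group2
haemorrhage,group3
hypertensive_disorders,group3
obstructed_labour,group3
embolism,group3
other_direct,other
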