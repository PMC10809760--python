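module_id	step_index	alternatives
M_CYTC	0	coxA
M_CYTC	1	coxB
M_CYTC	2	coxC,coxD
M_CBB3	0	ccoN
M_CBB3	1	ccoO
M_CBB3	2	ccoP
M_BD	0	cydA
M_BD	1	cydB
M_BD	2	appX,cydX
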