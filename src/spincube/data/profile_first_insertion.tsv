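label	energy_kJmol	note
RS_1	0	reactive state of the first S-insertion: AdoMet and octanoyl bound, main cluster reduced; profile reference
TS1_1	6	heterolytic C5'-SA cleavage transition state: reported barrier 6 above RS_1
IM_1	-42	5'-dA radical intermediate: cleavage reported exothermic by 42 from RS_1
TS2_1	-5	H6-abstraction transition state: reported barrier 37 above IM_1 (explicit point at -42+37)
PS_1	-184	first-insertion product, C6-S6 bond formed: reported 184 below the reactive state
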