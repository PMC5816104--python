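label	energy_kJmol	note
RS_2	0	second S-insertion reactive state BEFORE the one-electron reduction; profile reference
TS1_2	18	C5'-SA cleavage transition state without prior reduction: reported barrier 18
IM_2	-62	cleavage product without prior reduction: reported exothermic by 62
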