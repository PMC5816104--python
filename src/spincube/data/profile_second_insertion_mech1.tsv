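label	energy_kJmol	note
RS_2	0	second S-insertion reactive state after one-electron reduction; profile reference
IM1_2	-101	barrierless C5'-SA cleavage on reduction: reported 101 below reduced RS_2
TS2_2	-30	H8-abstraction transition state: reported barrier 71 above IM1_2 (explicit point at -101+71)
IM2_2	-125	C8 radical intermediate: reported 24 below IM1_2
IM2_2p	-105	rotated C8 radical (substrate turned about C6-C7): reported 20 above IM2_2
TS3_2	-63	S1-attack transition state (mechanism 1): reported barrier 42 above IM2_2p (explicit point at -105+42)
PS1_2	-69	mechanism-1 product (C8-S1 bond): reported -69 on the profile scale
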