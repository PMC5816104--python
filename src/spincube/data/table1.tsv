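label	family	column	energy_kJmol	note
↑↓↑↓ ↓↑↓↑	main_fixed	resting	0	relative QM/MM energy, resting state; main cluster fixed at [↑↓↑↓], zero reference of the block
↑↓↑↓ ↓↑↓↑	main_fixed	reactive	0	relative QM/MM energy, reactive state; main cluster fixed, zero reference of the block
↑↓↑↓ ↑↓↓↑	main_fixed	resting	-4.7	resting state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↑↓↓↑	main_fixed	reactive	23.7	reactive state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↑↑↓↓	main_fixed	resting	2.7	resting state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↑↑↓↓	main_fixed	reactive	37.4	reactive state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↓↓↑↑	main_fixed	resting	1.9	resting state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↓↓↑↑	main_fixed	reactive	0.4	reactive state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↓↑↑↓	main_fixed	resting	-5.9	resting state; shared row: main matches the fixed main pattern AND aux matches the fixed aux pattern
↑↓↑↓ ↓↑↑↓	main_fixed	reactive	-2.1	reactive state; shared row counted in both families by pattern matching
↑↓↑↓ ↑↓↑↓	main_fixed	resting	-0.9	resting state, main cluster fixed, auxiliary pattern varied
↑↓↑↓ ↑↓↑↓	main_fixed	reactive	21.2	reactive state, main cluster fixed, auxiliary pattern varied
↓↑↑↓ ↓↑↑↓	aux_fixed	resting	-19.3	resting state; auxiliary cluster fixed at [↓↑↑↓], main pattern varied
↓↑↑↓ ↓↑↑↓	aux_fixed	reactive	1.8	reactive state, auxiliary cluster fixed, main pattern varied
↓↓↑↑ ↓↑↑↓	aux_fixed	resting	-18.9	resting state, auxiliary cluster fixed, main pattern varied
↓↓↑↑ ↓↑↑↓	aux_fixed	reactive	NA	reactive state: geometry optimisation cleaved the AdoMet S-C bond, state could not be converged
↑↑↓↓ ↓↑↑↓	aux_fixed	resting	-17.7	resting state, auxiliary cluster fixed, main pattern varied
↑↑↓↓ ↓↑↑↓	aux_fixed	reactive	-9.1	reactive state; lowest reactive energy (the reactive spin state, RSS)
↑↓↓↑ ↓↑↑↓	aux_fixed	resting	-14.4	resting state, auxiliary cluster fixed, main pattern varied
↑↓↓↑ ↓↑↑↓	aux_fixed	reactive	0.7	reactive state, auxiliary cluster fixed, main pattern varied
↓↑↓↑ ↓↑↑↓	aux_fixed	resting	-7.6	resting state, auxiliary cluster fixed, main pattern varied
↓↑↓↑ ↓↑↑↓	aux_fixed	reactive	5.1	reactive state, auxiliary cluster fixed, main pattern varied
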