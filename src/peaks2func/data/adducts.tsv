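name	nmer	mass_shift	charge	mode
M+H	1	1.007276	1	positive
M+Na	1	22.989218	1	positive
M+K	1	38.963158	1	positive
M+NH4	1	18.033823	1	positive
M+2H	1	2.014552	2	positive
M+H-H2O	1	-17.003289	1	positive
2M+H	2	1.007276	1	positive
M-H	1	-1.007276	-1	negative
M+Cl	1	34.969402	-1	negative
M-H-H2O	1	-19.017841	-1	negative
M-2H	1	-2.014552	-2	negative
2M-H	2	-1.007276	-1	negative
M+FA-H	1	44.998201	-1	negative
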