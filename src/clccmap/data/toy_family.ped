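FAM1	F	0	0	1	1
FAM1	M	0	0	2	1
FAM1	IND12	F	M	1	2
FAM1	IND17	F	M	2	2
FAM1	IND13	F	M	1	1
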