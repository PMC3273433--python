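# X-chromosome mis-segregation scoring, experiment 2: catalytic mutant and rescue.
label	mothers	total_progeny	n_x0_sons	n_xxy_daughters
None	55	1245	119	88
OsSPO11D-Y213F	57	1994	175	129
DmSPO11	22	3434	3	3
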