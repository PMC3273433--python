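# X-chromosome mis-segregation scoring, experiment 1: progeny classes per transgene.
label	mothers	total_progeny	n_x0_sons	n_xxy_daughters
None	99	1283	146	106
AtSPO11-1	74	1204	138	95
AtSPO11-2	71	1187	178	88
OsSPO11D	97	1384	184	106
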