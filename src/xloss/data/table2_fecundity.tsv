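# Fecundity of mei-W68-1 crosses: eggs laid and pupae generated per genotype/transgene.
label	mothers	eggs	pupae
het_none	37	3768	3309
hom_none	107	6109	1568
hom_DmSPO11	11	1207	1047
hom_AtSPO11-1	40	2880	691
hom_AtSPO11-2	20	1536	359
hom_OsSPO11D	60	3577	753
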