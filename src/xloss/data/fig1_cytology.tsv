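# Oocyte-nucleus cytology counts: DSB signal (stage 2-8) and karyosome defect (stage 3-8).
label	endpoint	stage_range	n_positive	n_total	ovaries
het_control	dsb_signal	2-8	344	345	3
hom_none	dsb_signal	2-8	16	220	2
hom_DmSPO11	dsb_signal	2-8	180	180	2
het_control	karyosome_defect	3-8	254	278	3
hom_none	karyosome_defect	3-8	2	177	2
hom_DmSPO11	karyosome_defect	3-8	93	132	2
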