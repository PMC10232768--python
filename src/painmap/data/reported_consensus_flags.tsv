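region	correlation	cnn	gcnn
superior_frontal	1	1	1
precentral	1	1	1
superior_temporal	1	1	1
fusiform	1	1	1
supramarginal	1	1	1
insula	1	1	1
lateral_orbitofrontal	1	1	0
thalamus	1	1	0
rostral_middle_frontal	1	1	0
lateral_occipital	1	1	0
lingual	1	1	0
inferior_temporal	1	1	0
pars_opercularis	1	1	0
parahippocampal	1	0	1
bankssts	1	0	1
precuneus	1	0	1
rostral_anterior_cingulate	1	0	1
caudate	0	1	1
hippocampus	0	1	1
putamen	0	1	1
inferior_parietal	0	1	1
dacc	0	1	1
postcentral	0	1	1
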