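region	x_mm	y_mm	z_mm	volume_voxels	volume_mm3	peak_t
parahippocampal	21	-22	-26	255	6885	3.9
entorhinal	-21	-16	-29	455	12285	3.67
bankssts	63	-31	7	69	1863	3.35
bankssts	-48	-49	1	135	3645	2.65
lateral_occipital	42	-70	-5	531	14337	3.32
lateral_orbitofrontal	15	23	-20	46	1242	2.95
supramarginal	-39	-40	34	1032	27864	2.91
insula	-24	17	16	453	12231	2.74
superior_frontal	21	14	58	31	837	2.52
inferior_temporal	48	-52	-26	53	1431	2.4
inferior_temporal	-54	-16	-35	14	378	2.15
inferior_temporal	45	-52	-8	12	324	2.04
middle_temporal	-63	-22	-2	15	405	2.18
paracentral	-12	-16	46	15	405	2.18
precentral	12	-16	70	18	486	2.16
precentral	-9	-25	70	20	540	2.14
precentral	9	-37	70	12	324	2.02
precuneus	-12	-64	43	34	918	2.14
pars_opercularis	39	5	28	12	324	2.1
rostral_anterior_cingulate	-9	35	-2	14	378	2.04
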