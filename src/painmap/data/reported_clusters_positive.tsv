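region	x_mm	y_mm	z_mm	volume_voxels	volume_mm3	peak_t
superior_frontal	3	44	31	203	5481	3.74
superior_frontal	-27	-7	61	60	1620	2.34
superior_frontal	15	65	7	14	378	2.1
superior_frontal	6	-4	49	110	2970	2.08
lateral_orbitofrontal	30	20	-11	97	2619	3.14
lateral_orbitofrontal	-33	20	-11	18	486	2.22
precentral	54	14	25	40	1080	2.76
precentral	-33	-25	49	28	756	2.41
thalamus	12	-10	16	41	1107	2.64
thalamus	3	-16	-5	10	270	2.46
rostral_middle_frontal	-21	47	31	26	702	2.59
frontal_pole	-6	62	-11	35	945	2.41
lateral_occipital	-45	-76	-2	22	594	2.34
superior_temporal	-48	-1	-5	17	459	2.3
fusiform	27	-49	-20	13	351	2.16
lingual	6	-58	4	17	459	2.01
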