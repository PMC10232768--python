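method	true_low_pred_low	true_low_pred_high	true_high_pred_low	true_high_pred_high
cnn	8917	2724	2297	4340
gcnn	9793	1512	3422	2959
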