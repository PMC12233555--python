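outcome	n_tested	n_nominal	n_fdr_significant	inflation_factor	n_strong_coloc
AD	3610	420	78	1.36	27
PD	2757	204	10	1.07	2
ALS	3518	278	17	1.28	3
MS	3492	377	64	1.41	29
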