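screen	n_tests	n_discoveries	alpha
plasma_pqtl	13377	169	0.05
plasma_eqtl	7259	90	0.05
brain_eqtl	16991	188	0.05
imaging	41738	101	0.05
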