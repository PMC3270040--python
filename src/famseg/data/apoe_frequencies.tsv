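group	apoe4_allele_freq
familial_cases	0.7213
sporadic_cases	0.60
controls	0.26
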