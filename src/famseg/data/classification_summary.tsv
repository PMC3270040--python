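gene	provenance	category	n_mut	n_fam
APP	previously_reported	NOT_PATHOGENIC	1	1
APP	novel	LIKELY_PATHOGENIC	1	1
APP	novel	UNKNOWN	2	2
APP	novel	NOT_PATHOGENIC	2	3
PSEN1	previously_reported	PATHOGENIC	2	7
PSEN1	novel	UNKNOWN	1	1
PSEN2	previously_reported	UNKNOWN	3	13
MAPT	previously_reported	UNKNOWN	1	1
MAPT	novel	LIKELY_PATHOGENIC	1	1
MAPT	novel	UNKNOWN	1	1
MAPT	novel	NOT_PATHOGENIC	4	12
GRN	previously_reported	PATHOGENIC	3	3
GRN	previously_reported	UNKNOWN	1	1
GRN	previously_reported	NOT_PATHOGENIC	4	4
GRN	novel	LIKELY_PATHOGENIC	1	2
GRN	novel	UNKNOWN	3	4
GRN	novel	NOT_PATHOGENIC	2	3
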