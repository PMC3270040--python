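gene	change	variant_class	novelty	prior_db_status	prediction	splice_wt	splice_mut	maf	count:familial_probands:case	count:sporadic_ad:case	count:controls:control	count:unselected_gsk:unselected	frequency_group	printed_category	n_fam
PSEN1	A79V	missense	previously_reported	pathogenic	probably_damaging	NA	NA	0.0046	4/439	1/1806	0/1346		known_pathogenic	PATHOGENIC	4
PSEN1	G206A	missense	previously_reported	pathogenic	probably_damaging	NA	NA	0.0034	3/439	0/1806	0/1346		known_pathogenic	PATHOGENIC	3
GRN	R110X	nonsense	previously_reported	pathogenic	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346		known_pathogenic	PATHOGENIC	1
GRN	R493X	nonsense	previously_reported	pathogenic	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346		known_pathogenic	PATHOGENIC	1
APP	N660Y	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346	0/12481	likely_pathogenic	LIKELY_PATHOGENIC	1
MAPT	G201S	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	1/1806	0/1346		likely_pathogenic	LIKELY_PATHOGENIC	1
GRN	c.1414-1G>T	splice_site	novel	absent	probably_damaging	1.00	0.00	0.0023	2/439	0/1806	0/1346		likely_pathogenic	LIKELY_PATHOGENIC	2
GRN	G515A	missense	previously_reported	not_pathogenic	probably_damaging	NA	NA	0.0011	1/439	1/1806	0/1346		likely_pathogenic	PATHOGENIC	1
APP	G322A	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346	0/12481	likely_non_pathogenic	NOT_PATHOGENIC	1
APP	E599K	missense	novel	absent	na	NA	NA	0.0023	2/439	2/1806	2/1346		likely_non_pathogenic	NOT_PATHOGENIC	2
APP	A673T	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	0/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
PSEN2	R62H	missense	previously_reported	unknown	na	NA	NA	0.0068	6/439	18/1806	13/1346		likely_non_pathogenic	UNKNOWN	6
PSEN2	R71W	missense	previously_reported	pathogenic	na	NA	NA	0.0068	6/439	26/1806	3/1346		likely_non_pathogenic	UNKNOWN	6
PSEN2	M174V	missense	previously_reported	pathogenic	na	NA	NA	0.0011	1/439	3/1806	0/1346		likely_non_pathogenic	UNKNOWN	1
MAPT	R5H	missense	previously_reported	pathogenic	na	NA	NA	0.0011	1/439	1/1806	0/1346		likely_non_pathogenic	UNKNOWN	1
MAPT	R168C	missense	novel	absent	na	NA	NA	0.0011	1/439	3/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
MAPT	A152T	missense	novel	absent	na	NA	NA	0.0057	5/439	17/1806	6/1346		likely_non_pathogenic	NOT_PATHOGENIC	5
MAPT	V224G	missense	novel	absent	na	NA	NA	0.0023	2/439	10/1806	12/1346		likely_non_pathogenic	NOT_PATHOGENIC	2
MAPT	A239T	missense	novel	absent	na	NA	NA	0.0046	4/439	4/1806	4/1346		likely_non_pathogenic	NOT_PATHOGENIC	4
GRN	P85A	missense	novel	absent	na	NA	NA	0.0023	2/439	0/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	2
GRN	V141I	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	0/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
GRN	T268M	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	1/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
GRN	A324T	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	5/1806	2/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
GRN	D376N	missense	novel	absent	na	NA	NA	0.0011	1/439	0/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
GRN	R433Q	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	0/1806	0/1346		likely_non_pathogenic	NOT_PATHOGENIC	1
APP	G191E	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346	0/12481	unknown	UNKNOWN	1
APP	V340M	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346	0/12481	unknown	UNKNOWN	1
PSEN1	P7L	missense	novel	absent	na	NA	NA	0.0011	1/439	0/1806	0/1346	0/12481	unknown	UNKNOWN	1
MAPT	S427F	missense	novel	absent	probably_damaging	NA	NA	0.0011	1/439	0/1806	0/1346		unknown	UNKNOWN	1
GRN	D135V	missense	novel	absent	na	NA	NA	0.0011	1/439	0/1806	0/1346		unknown	UNKNOWN	1
GRN	M207T	missense	previously_reported	unknown	na	NA	NA	0.0011	1/439	0/1806	0/1346		unknown	UNKNOWN	1
GRN	V514M	missense	novel	absent	na	NA	NA	0.0011	1/439	0/1806	0/1346		unknown	UNKNOWN	1
GRN	V519M	missense	novel	absent	probably_damaging	NA	NA	0.0023	2/439	2/1806	7/1346		unknown	UNKNOWN	2
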