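n_affected	n_families	n_variant_families
28	1	1
20	2	2
19	1	0
17	1	2
16	1	0
15	1	0
14	1	0
13	5	1
12	3	0
11	4	0
10	13	2
9	14	2
8	27	5
7	32	6
6	54	5
5	107	9
4	172	25
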