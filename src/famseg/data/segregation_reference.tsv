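variant_key	n_fam	affected_carriers	aff_carrier_aao_mean	aff_carrier_aao_sd	affected_noncarriers	aff_noncarrier_aao_mean	aff_noncarrier_aao_sd	unaffected_carriers	unaff_carrier_age_mean	unaff_carrier_age_sd	unaffected_noncarriers	unaff_noncarrier_age_mean	unaff_noncarrier_age_sd
APP:N660Y	1	3	61.6	3	0	NA	NA	1	62	NA	1	69	NA
PSEN1:A79V	4	10	68.9	8.5	1	77	NA	3	60	4.3	13	70.62	12.95
PSEN1:G206A	3	6	60.8	6.7	0	NA	NA	0	NA	NA	1	40	NA
MAPT:G201S	1	2	74	0	0	NA	NA	2	61	5.7	2	49	4.2
GRN:R110X	1	3	66.3	2.1	0	NA	NA	0	NA	NA	5	72.2	5.26
GRN:c.1414-1G>T	2	8	65.8	11.7	1	74	NA	0	NA	NA	1	70	NA
GRN:R493X	1	1	70	NA	3	78.3	1.15	4	56.3	4.04	3	56.3	11.06
GRN:G515A	1	3	80	7.5	0	NA	NA	0	NA	NA	1	66	NA
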