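family_id	individual_id	father_id	mother_id	sex	affection	age_onset	age_last_exam	diagnosis	apoe	proband	n_affected_reported	gt:APP:G322A	gt:APP:N660Y	gt:GRN:G515A	gt:GRN:R110X	gt:GRN:R493X	gt:GRN:c.1414-1G>T	gt:MAPT:G201S	gt:PSEN1:A79V	gt:PSEN1:G206A
F_A79V_1	F_A79V_1_01	0	0	1	2	76	NA	none	NA	1	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_02	0	0	2	2	70	NA	none	NA	0	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_03	0	0	1	2	62	NA	none	NA	0	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_04	0	0	2	2	77	NA	none	NA	0	28	.	.	.	.	.	.	.	-	.
F_A79V_1	F_A79V_1_05	0	0	1	1	NA	55.7	none	NA	0	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_06	0	0	2	1	NA	60	none	NA	0	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_07	0	0	1	1	NA	64.3	none	NA	0	28	.	.	.	.	.	.	.	+	.
F_A79V_1	F_A79V_1_08	0	0	2	1	NA	48	none	NA	0	28	.	.	.	.	.	.	.	-	.
F_A79V_1	F_A79V_1_09	0	0	1	1	NA	54	none	NA	0	28	.	.	.	.	.	.	.	-	.
F_A79V_1	F_A79V_1_10	0	0	2	1	NA	58	none	NA	0	28	.	.	.	.	.	.	.	-	.
F_A79V_1	F_A79V_1_11	0	0	1	1	NA	62	none	NA	0	28	.	.	.	.	.	.	.	-	.
F_A79V_2	F_A79V_2_01	0	0	1	2	56	NA	none	NA	1	5	.	.	.	.	.	.	.	+	.
F_A79V_2	F_A79V_2_02	0	0	2	2	60	NA	none	NA	0	5	.	.	.	.	.	.	.	+	.
F_A79V_2	F_A79V_2_03	0	0	1	2	64	NA	none	NA	0	5	.	.	.	.	.	.	.	+	.
F_A79V_2	F_A79V_2_04	0	0	2	1	NA	65	none	NA	0	5	.	.	.	.	.	.	.	-	.
F_A79V_2	F_A79V_2_05	0	0	1	1	NA	68	none	NA	0	5	.	.	.	.	.	.	.	-	.
F_A79V_2	F_A79V_2_06	0	0	2	1	NA	71	none	NA	0	5	.	.	.	.	.	.	.	-	.
F_A79V_3	F_A79V_3_01	0	0	1	2	68	NA	none	NA	1	4	.	.	.	.	.	.	.	+	.
F_A79V_3	F_A79V_3_02	0	0	2	2	72	NA	none	NA	0	4	.	.	.	.	.	.	.	+	.
F_A79V_3	F_A79V_3_03	0	0	1	1	NA	74	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_A79V_3	F_A79V_3_04	0	0	2	1	NA	77	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_A79V_3	F_A79V_3_05	0	0	1	1	NA	80	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_A79V_4	F_A79V_4_01	0	0	1	2	80	NA	none	NA	1	4	.	.	.	.	.	.	.	+	.
F_A79V_4	F_A79V_4_02	0	0	2	2	81	NA	none	NA	0	4	.	.	.	.	.	.	.	+	.
F_A79V_4	F_A79V_4_03	0	0	1	1	NA	84	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_A79V_4	F_A79V_4_04	0	0	2	1	NA	88	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_A79V_4	F_A79V_4_05	0	0	1	1	NA	89.1	none	NA	0	4	.	.	.	.	.	.	.	-	.
F_G206A_1	F_G206A_1_01	0	0	1	2	51.7	NA	none	NA	1	4	.	.	.	.	.	.	.	.	+
F_G206A_1	F_G206A_1_02	0	0	2	2	56	NA	none	NA	0	4	.	.	.	.	.	.	.	.	+
F_G206A_1	F_G206A_1_03	0	0	1	1	NA	40	none	NA	0	4	.	.	.	.	.	.	.	.	-
F_G206A_2	F_G206A_2_01	0	0	1	2	59	NA	none	NA	1	4	.	.	.	.	.	.	.	.	+
F_G206A_2	F_G206A_2_02	0	0	2	2	62	NA	none	NA	0	4	.	.	.	.	.	.	.	.	+
F_G206A_3	F_G206A_3_01	0	0	1	2	66	NA	none	NA	1	4	.	.	.	.	.	.	.	.	+
F_G206A_3	F_G206A_3_02	0	0	2	2	70.1	NA	none	NA	0	4	.	.	.	.	.	.	.	.	+
F_N660Y_1	F_N660Y_1_01	0	0	1	2	58.6	NA	none	NA	1	4	.	+	.	.	.	.	.	.	.
F_N660Y_1	F_N660Y_1_02	0	0	2	2	61.6	NA	none	NA	0	4	.	+	.	.	.	.	.	.	.
F_N660Y_1	F_N660Y_1_03	0	0	1	2	64.6	NA	none	NA	0	4	.	+	.	.	.	.	.	.	.
F_N660Y_1	F_N660Y_1_04	0	0	2	1	NA	62	none	NA	0	4	.	+	.	.	.	.	.	.	.
F_N660Y_1	F_N660Y_1_05	0	0	1	1	NA	69	none	NA	0	4	.	-	.	.	.	.	.	.	.
F_G201S_1	F_G201S_1_01	0	0	1	2	74	NA	none	NA	1	4	.	.	.	.	.	.	+	.	.
F_G201S_1	F_G201S_1_02	0	0	2	2	74	NA	none	NA	0	4	.	.	.	.	.	.	+	.	.
F_G201S_1	F_G201S_1_03	0	0	1	1	NA	57	none	NA	0	4	.	.	.	.	.	.	+	.	.
F_G201S_1	F_G201S_1_04	0	0	2	1	NA	65	none	NA	0	4	.	.	.	.	.	.	+	.	.
F_G201S_1	F_G201S_1_05	0	0	1	1	NA	46	none	NA	0	4	.	.	.	.	.	.	-	.	.
F_G201S_1	F_G201S_1_06	0	0	2	1	NA	52	none	NA	0	4	.	.	.	.	.	.	-	.	.
F_R110X_1	F_R110X_1_01	0	0	1	2	64.2	NA	none	NA	1	4	.	.	.	+	.	.	.	.	.
F_R110X_1	F_R110X_1_02	0	0	2	2	66.3	NA	none	NA	0	4	.	.	.	+	.	.	.	.	.
F_R110X_1	F_R110X_1_03	0	0	1	2	68.4	NA	none	NA	0	4	.	.	.	+	.	.	.	.	.
F_R110X_1	F_R110X_1_04	0	0	2	1	NA	65.8	none	NA	0	4	.	.	.	-	.	.	.	.	.
F_R110X_1	F_R110X_1_05	0	0	1	1	NA	69	none	NA	0	4	.	.	.	-	.	.	.	.	.
F_R110X_1	F_R110X_1_06	0	0	2	1	NA	72	none	NA	0	4	.	.	.	-	.	.	.	.	.
F_R110X_1	F_R110X_1_07	0	0	1	1	NA	75	none	NA	0	4	.	.	.	-	.	.	.	.	.
F_R110X_1	F_R110X_1_08	0	0	2	1	NA	79.2	none	NA	0	4	.	.	.	-	.	.	.	.	.
F_1414_1	F_1414_1_01	0	0	1	2	47.8	NA	none	NA	1	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_02	0	0	2	2	55	NA	none	NA	0	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_03	0	0	1	2	60	NA	none	NA	0	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_04	0	0	2	2	63	NA	none	NA	0	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_05	0	0	1	2	68	NA	none	NA	0	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_06	0	0	2	2	72	NA	none	NA	0	20	.	.	.	.	.	+	.	.	.
F_1414_1	F_1414_1_07	0	0	1	2	74	NA	none	NA	0	20	.	.	.	.	.	-	.	.	.
F_1414_1	F_1414_1_08	0	0	2	1	NA	70	none	NA	0	20	.	.	.	.	.	-	.	.	.
F_1414_2	F_1414_2_01	0	0	1	2	78	NA	none	NA	1	4	.	.	.	.	.	+	.	.	.
F_1414_2	F_1414_2_02	0	0	2	2	82.6	NA	none	NA	0	4	.	.	.	.	.	+	.	.	.
F_R493X_1	F_R493X_1_01	0	0	1	2	70	NA	none	NA	1	5	.	.	.	.	+	.	.	.	.
F_R493X_1	F_R493X_1_02	0	0	2	2	77.2	NA	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_R493X_1	F_R493X_1_03	0	0	1	2	78.2	NA	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_R493X_1	F_R493X_1_04	0	0	2	2	79.5	NA	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_R493X_1	F_R493X_1_05	0	0	1	1	NA	51.5	none	NA	0	5	.	.	.	.	+	.	.	.	.
F_R493X_1	F_R493X_1_06	0	0	2	1	NA	55	none	NA	0	5	.	.	.	.	+	.	.	.	.
F_R493X_1	F_R493X_1_07	0	0	1	1	NA	58	none	NA	0	5	.	.	.	.	+	.	.	.	.
F_R493X_1	F_R493X_1_08	0	0	2	1	NA	60.7	none	NA	0	5	.	.	.	.	+	.	.	.	.
F_R493X_1	F_R493X_1_09	0	0	1	1	NA	45.4	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_R493X_1	F_R493X_1_10	0	0	2	1	NA	56	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_R493X_1	F_R493X_1_11	0	0	1	1	NA	67.5	none	NA	0	5	.	.	.	.	-	.	.	.	.
F_G515A_1	F_G515A_1_01	0	0	1	2	72.5	NA	none	NA	1	4	.	.	+	.	.	.	.	.	.
F_G515A_1	F_G515A_1_02	0	0	2	2	80	NA	none	NA	0	4	.	.	+	.	.	.	.	.	.
F_G515A_1	F_G515A_1_03	0	0	1	2	87.5	NA	none	NA	0	4	.	.	+	.	.	.	.	.	.
F_G515A_1	F_G515A_1_04	0	0	2	1	NA	66	none	NA	0	4	.	.	-	.	.	.	.	.	.
F_G322A_1	F_G322A_1_01	0	0	1	2	60	NA	none	NA	1	11	+	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_02	0	0	2	2	65	NA	none	NA	0	11	+	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_03	0	0	1	2	70	NA	none	NA	0	11	+	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_04	0	0	2	2	75	NA	none	NA	0	11	+	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_05	0	0	1	2	58	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_06	0	0	2	2	62	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_07	0	0	1	2	64	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_08	0	0	2	2	66	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_09	0	0	1	2	70	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_10	0	0	2	2	72	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
F_G322A_1	F_G322A_1_11	0	0	1	2	76	NA	none	NA	0	11	-	.	.	.	.	.	.	.	.
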