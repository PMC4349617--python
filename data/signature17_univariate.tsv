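transcript	classification_ability_pct	rank_acc	dfs_area_pct	rank_asurv	rank_p
CCL16	74.36	1	43.58	2	5
GLI3	71.79	2	34.43	6	15
TUB	71.79	3	35.71	4	13
PRKCB1-1	70.51	4	34.51	5	3
ZAP70	67.95	5	29.53	8	14
ELF5	67.95	6	26.70	10	17
EDN1	66.67	7	31.09	7	9
SF1	66.67	8	25.87	11	8
CREG1	66.67	9	23.40	14	2
MAST1	65.38	10	23.71	13	12
CSNK1A1	64.10	11	24.95	12	11
HDAC9	64.10	12	27.78	9	10
MAK	62.82	13	38.76	3	4
CCL15	61.54	14	22.94	15	6
PRKCB1-2	61.54	15	16.73	17	1
CDKN2AIP	61.54	16	46.00	1	16
FOXE1-1	60.26	17	19.60	16	7
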