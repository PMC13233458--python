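Genotype	SIRE	Ale	Ty1_other	Tekay	Retand	Athila	Ty3_other	LINE	Pararetrovirus	EnSpm_CACTA	DNA_other	rDNA	satDNA	Unclassified	Total
SoffBla	12.13	0.95	1.68	18.10	3.83	2.62	1.31	0.47	0.07	0.92	0.57	1.01	3.29	4.61	51.56
SoffBad	11.94	1.07	1.66	18.82	3.99	2.64	1.93	0.58	0.07	1.01	0.99	1.23	2.84	3.48	52.25
SoffLOE	12.33	1.28	1.92	18.82	4.00	2.84	2.15	0.61	0.06	1.00	1.03	1.64	2.35	2.49	52.52
SrobNG2	11.43	1.04	1.63	18.38	3.61	2.56	1.90	0.47	0.07	0.97	0.73	0.23	2.81	4.89	50.72
SrobIJ7	11.07	1.17	1.65	17.70	3.62	2.61	2.37	0.56	0.04	1.06	0.78	1.53	2.82	2.98	49.96
SeduE2.	11.06	0.96	1.52	16.52	3.81	1.83	2.39	1.06	0	0.85	0.62	0.95	4.67	2.37	48.61
SeduIJ7	11.39	0.94	2.08	16.77	3.84	1.90	1.91	0.79	0	1.64	0.50	1.04	4.66	3.14	50.60
SbarChu	10.06	1.20	1.52	15.39	3.62	3.48	1.95	0.40	0.02	0.81	0.76	1.56	3.20	4.57	48.54
SbarTEK	10.61	1.14	1.45	15.24	3.67	3.35	2.17	0.86	0.06	0.92	0.91	1.99	3.54	2.78	48.69
SsinUba	10.66	0.94	1.58	13.81	3.11	3.09	1.52	0.39	0	0.92	0.53	1.77	3.70	3.94	45.96
SsinKac	11.13	1.21	1.45	14.44	3.44	2.93	2.30	0.66	0	0.77	0.71	2.16	5.26	3.11	49.57
Sspo517	9.11	1.35	0.89	10.29	3.97	3.66	2.35	0.30	0.03	0.97	0.75	1.00	4.66	4.52	43.85
SspoGla	9.14	1.40	1.29	10.13	3.50	4.00	2.46	1.11	0.04	0.93	0.75	0.73	4.62	2.82	42.92
Sspo196	7.76	0.96	1.53	10.60	2.76	5.73	3.70	0.36	0.06	0.85	1.38	0.28	6.35	3.28	45.60
SspoMan	8.35	1.71	1.71	10.34	4.13	4.59	2.53	0.48	0	1.07	0.99	1.1	3.89	2.69	43.58
SspoNp-X	7.88	1.23	1.77	12.10	3.19	5.41	3.14	0.76	0.06	0.75	0.69	0.75	3.73	4.62	46.08
cvSP803	11.88	0.75	1.52	15.45	2.02	6.79	3.66	0.75	0.08	1.32	0.52	0.03	5.16	4.04	53.96
cvR570.	11.90	0.72	1.70	18.15	3.28	3.60	2.22	1.03	0.10	1.33	1.07	0.88	2.63	1.76	50.37
cvQ208.	9.67	2.00	2.41	17.38	4.51	2.83	4.31	0.38	0.05	1.02	0.66	2.38	0.70	3.42	51.71
cvQ241.	10.09	1.04	1.97	16.57	3.50	2.96	1.91	0.51	0.05	0.91	1.01	1.42	3.98	2.90	48.82
cvCO213	11.09	1.22	1.64	17.24	3.72	3.41	2.18	0.98	0.05	0.96	0.67	1.72	3.08	2.46	50.42
cvCO285	10.56	1.24	1.39	14.11	3.99	3.09	2.26	0.55	0	0.84	0.57	1.60	4.76	4.01	48.97
cvKasso	10.13	1.02	1.48	15.11	3.68	3.08	2.08	0.45	0.06	0.87	0.72	1.41	4.30	3.08	47.47
cvNA567	10.79	1.03	1.60	16.48	3.61	3.11	2.39	0.47	0.06	0.98	0.79	1.36	2.69	3.46	48.82
cvPOJ28	11.25	0.98	1.61	17.04	3.68	2.61	1.73	0.90	0.09	0.82	0.61	1.17	3.91	3.05	49.45
cvRagna	11.17	0.99	1.58	17.33	3.33	3.03	2.29	0.52	0.06	1.02	0.97	1.03	2.72	2.61	48.65
Snareng	4.80	0.12	2.00	8.72	6.18	5.65	1.81	0.51	0.02	1.96	0.68	0.86	5.00	4.18	42.50
EfulEFO	4.73	0.23	1.19	11.83	7.87	6.50	1.45	0	0	1.69	0.48	0.88	2.63	4.96	44.44
MfloPI2	8.68	0.19	2.45	14.37	12.30	1.64	6.17	0.33	0.09	4.45	0.70	0.67	4.46	3.23	59.74
MsinNG7	7.52	0.55	2.36	11.27	13.16	0.92	4.11	0.28	0	4.31	0.41	0.58	4.82	5.17	55.46
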