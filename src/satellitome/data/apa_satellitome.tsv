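name	rul	at_percent	v	superfamily	divergence_0b	divergence_1b	abundance_0b	abundance_1b	log2_printed
ApaSat01-51	51	54.9	8		5.69	5.53	6.306	4.697	-0.421
ApaSat02-236	236	64.8	1	1	14.99	15.16	0.448	0.371	-0.27
ApaSat03-91	91	51.6	5		4.96	4.9	0.23	0.185	-0.321
ApaSat04-233	233	63.1	1	1	17.43	17	0.166	0.138	-0.27
ApaSat05-23	23	52.2	2		6.61	6.47	0.165	0.076	-1.11
ApaSat06-86	86	46.4	1		4.95	4.62	0.084	0.157	0.91
ApaSat07-6-tel	6	50.0	1		9.7	8.6	0.067	0.095	0.51
ApaSat08-35	35	62.9	3		6.15	6.33	0.066	0.043	-0.60
ApaSat09-21	21	75.0	2		14.88	14.66	0.06	0.053	-0.18
ApaSat10-179	179	63.1	1		4.02	3.95	0.053	0.05	-0.10
ApaSat11-22	22	50.0	1		11.36	10	0.053	0.048	-0.13
ApaSat12-69	69	60.9	1		3.5	3.61	0.052	0.05	-0.06
ApaSat13-22	22	56.5	3		10.6	9.59	0.049	0.007	-2.86
ApaSat14-184	184	63.0	2		11.78	11.69	0.045	0.054	0.25
ApaSat15-51	51	54.9	2		6.41	6.34	0.043	0.037	-0.21
ApaSat16-54	54	48.1	2		9.4	9.26	0.042	0.046	0.14
ApaSat17-365	365	51.8	1		2.24	2.18	0.04	0.046	0.20
ApaSat18-58	58	46.6	2		6.95	7.65	0.034	0.033	-0.04
ApaSat19-77	77	66.2	1		5.15	4.88	0.034	0.043	0.32
ApaSat20-18	18	50.0	1		12.04	8.08	0.033	0.181	2.43
ApaSat21-68	68	48.5	1		1.7	1.65	0.023	0.009	-1.28
ApaSat22-63	63	56.5	1		16.48	16.19	0.021	0.026	0.32
ApaSat23-37	37	43.2	1		3.75	3.95	0.02	0.006	-1.68
ApaSat24-78	78	56.4	1		5.73	5.77	0.019	0.013	-0.49
ApaSat25-27	27	51.9	1		10.93	10.33	0.018	0.021	0.27
ApaSat26-195	195	65.1	1		8.24	9.67	0.017	0.012	-0.51
ApaSat27-178	178	39.9	1		7.21	7.66	0.016	0.014	-0.17
ApaSat28-52	52	55.8	1		16.19	16.11	0.015	0.017	0.16
ApaSat29-52	52	67.3	1		13.15	13.11	0.015	0.014	-0.10
ApaSat30-50	50	64.0	1		15.45	14.47	0.015	0.014	-0.04
ApaSat31-165	165	63.0	1		9.34	9.62	0.014	0.011	-0.31
ApaSat32-85	85	58.8	1		6.86	16.12	0.013	0.001	-4.63
ApaSat33-112	112	64.3	1		4.83	3.97	0.013	0.023	0.85
ApaSat34-59	59	37.3	1		1.48	1.44	0.012	0.104	3.07
ApaSat35-37	37	48.6	1		4.63	4.82	0.012	0.009	-0.42
ApaSat36-21	21	57.1	1		6.32	6.87	0.011	0.01	-0.24
ApaSat37-38	38	57.9	2		5.01	4.76	0.011	0.01	-0.06
ApaSat38-107	107	41.1	1		17.94	15.1	0.011	0.018	0.79
ApaSat39-32	32	50.0	1		7.32	12.1	0.01	0.001	-4.00
ApaSat40-189	189	65.6	1		9.63	7.7	0.009	0.027	1.53
ApaSat41-33	33	30.3	1		10.07	9.5	0.008	0.011	0.41
ApaSat42-90	90	66.7	1		4.76	4.67	0.006	0.006	-0.06
ApaSat43-61	61	68.9	1		10.15	7.67	0.006	0.015	1.37
ApaSat44-21	21	38.1	1		25.9	25.43	0.002	0.041	4.34
ApaSat45-113	113	75.1	1		2.78	1.49	0.001	0.007	2.41
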