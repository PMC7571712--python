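protein	mean0	sd0	mean1	sd1	adj_p	rank
WFDC2	7.35	0.71	8.15	0.75	<0.001	1
MUC-16	4.67	1.93	6.26	1.54	<0.001	2
ITGAV	3.37	0.27	3.08	0.35	0.002	3
MK	7.11	0.88	7.86	0.92	0.002	4
VEGFR-2	7.13	0.28	6.85	0.35	0.002	5
FR-alpha	6.99	0.75	8.05	1.41	0.002	6
DNER	8.01	0.37	7.63	0.49	0.002	7
CTSV	3.75	0.70	3.19	0.70	0.002	8
CXCL13	8.37	0.78	9.02	0.82	0.002	9
WISP-1	4.45	0.61	5.06	0.81	0.003	10
IL6	4.03	1.31	5.15	1.51	0.003	11
CXCL1	7.56	1.42	8.55	1.30	0.004	12
CCL23	10.03	0.51	10.42	0.54	0.004	13
CXCL11	8.06	1.27	9.12	1.55	0.007	14
TNFRSF6B	4.33	0.70	4.90	0.86	0.008	15
CDCP1	3.52	0.72	4.09	0.88	0.010	16
IL10	3.03	0.60	3.61	0.92	0.011	17
IL-10RB	6.73	0.34	7.00	0.42	0.012	18
SCF	9.67	0.51	9.19	0.78	0.012	19
VEGFA	9.85	0.58	10.34	0.80	0.013	20
CD40	9.91	0.69	10.47	0.90	0.014	21
CXCL6	7.45	1.32	8.37	1.46	0.014	22
ICOSLG	3.90	0.29	3.67	0.39	0.015	23
IL-18R1	7.07	0.47	7.38	0.51	0.015	24
IL-17C	1.44	0.66	2.17	1.26	0.015	25
CCL3	4.88	0.70	5.45	0.96	0.015	26
PD-L1	3.78	0.45	4.13	0.60	0.015	27
MMP-1	12.26	1.39	13.30	1.76	0.015	28
TNFRSF4	3.34	0.60	3.75	0.69	0.015	29
ABL1	2.76	1.62	4.16	2.42	0.015	30
LYPD3	4.08	0.47	3.73	0.58	0.015	31
SCAMP3	2.98	1.80	4.39	2.40	0.015	32
IL-15RA	0.34	0.18	0.48	0.24	0.015	33
TNFSF14	4.52	0.76	5.15	1.13	0.018	34
TXLNA	3.96	1.91	5.36	2.46	0.018	35
CSF-1	8.16	0.30	8.33	0.29	0.018	36
IL8	6.21	1.28	6.90	1.17	0.019	37
DKN1A	2.30	2.31	3.96	2.97	0.019	38
RSPO3	3.80	0.61	4.28	0.86	0.019	39
LYN	1.14	1.10	1.85	1.28	0.024	40
MCP-1	10.12	0.56	10.49	0.69	0.024	41
LAP TGF-beta-1	7.49	0.69	7.96	0.87	0.025	42
PVRL4	6.09	0.63	6.63	1.01	0.025	43
TFPI-2	7.78	0.61	8.22	0.81	0.026	44
IL7	3.53	1.23	4.27	1.38	0.026	45
MCP-4	3.69	1.12	4.29	1.11	0.026	46
EGF	6.18	2.23	7.57	2.62	0.026	47
CXCL9	7.68	1.23	8.31	1.17	0.029	48
CEACAM1	7.55	0.17	7.43	0.23	0.030	49
ADAM-TS 15	4.32	0.58	4.68	0.69	0.033	50
FASLG	8.91	0.57	8.61	0.58	0.033	51
OPG	10.65	0.31	10.89	0.49	0.036	52
CCL4	6.42	0.61	6.87	0.95	0.041	53
CXCL5	9.69	2.15	10.70	2.02	0.046	54
IL-12B	4.40	0.69	4.76	0.74	0.046	55
ESM-1	8.92	0.47	9.19	0.57	0.047	56
SIRT2	3.30	2.00	4.50	2.53	0.048	57
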