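protein	mean0	sd0	mean1	sd1	adj_p	rank
WFDC2	7.37	0.72	8.33	0.64	<0.001	1
MUC-16	4.73	1.93	6.55	1.40	<0.001	2
MK	7.15	0.86	8.04	0.84	<0.001	3
FR-alpha	7.00	0.75	8.31	1.36	<0.001	4
ITGAV	3.38	0.27	3.05	0.34	<0.001	5
DNER	8.03	0.37	7.57	0.48	<0.001	6
IL6	4.07	1.31	5.35	1.40	<0.001	7
CDCP1	3.55	0.72	4.26	0.81	<0.001	8
VEGFR-2	7.13	0.28	6.82	0.35	0.001	9
IL10	3.02	0.61	3.76	0.88	0.001	10
CXCL13	8.38	0.80	9.10	0.84	0.001	11
WISP-1	4.48	0.60	5.16	0.81	0.001	12
TNFRSF6B	4.32	0.71	5.03	0.85	0.001	13
CTSV	3.76	0.71	3.14	0.71	0.001	14
CCL23	10.04	0.51	10.48	0.52	0.001	15
CXCL1	7.66	1.34	8.67	1.22	0.002	16
SCF	9.69	0.52	9.09	0.79	0.002	17
TNFRSF4	3.32	0.60	3.85	0.69	0.002	18
CXCL11	8.10	1.27	9.29	1.58	0.002	19
VEGFA	9.88	0.56	10.45	0.79	0.003	20
CD40	9.93	0.68	10.55	0.88	0.005	21
IL-10RB	6.74	0.34	7.04	0.42	0.005	22
CSF-1	8.17	0.30	8.38	0.28	0.005	23
TNFSF14	4.53	0.77	5.26	1.08	0.005	24
CCL3	4.91	0.70	5.54	0.92	0.005	25
SCAMP3	3.03	1.82	4.61	2.33	0.006	26
CXCL6	7.53	1.29	8.50	1.42	0.006	27
ABL1	2.79	1.63	4.32	2.37	0.008	28
TXLNA	4.01	1.92	5.58	2.42	0.008	29
IL-17C	1.48	0.63	2.30	1.32	0.008	30
PVRL4	6.10	0.65	6.75	1.03	0.008	31
IL8	6.26	1.26	7.04	1.13	0.008	32
IL-18R1	7.05	0.47	7.41	0.55	0.008	33
RSPO3	3.81	0.61	4.37	0.89	0.008	34
TFPI-2	7.78	0.63	8.31	0.82	0.008	35
MCP-1	10.14	0.55	10.58	0.69	0.008	36
CXCL9	7.70	1.24	8.46	1.13	0.008	37
ICOSLG	3.90	0.29	3.65	0.39	0.008	38
PD-L1	3.79	0.45	4.18	0.61	0.008	39
TNFRSF9	6.20	0.63	6.66	0.73	0.008	40
IL-15RA	0.35	0.18	0.50	0.24	0.008	41
DKN1A	2.36	2.33	4.19	2.95	0.009	42
LYN	1.17	1.11	1.94	1.27	0.011	43
LYPD3	4.07	0.48	3.70	0.61	0.011	44
FASLG	8.90	0.57	8.54	0.57	0.012	45
ADAM-TS 15	4.33	0.58	4.76	0.71	0.012	46
OPG	10.66	0.30	10.94	0.48	0.012	47
ESM-1	8.92	0.48	9.25	0.56	0.014	48
MMP-1	12.32	1.37	13.36	1.84	0.018	49
EGF	6.25	2.23	7.74	2.62	0.018	50
SYND1	6.46	0.67	6.94	0.85	0.018	51
MSLN	2.18	0.88	2.89	1.33	0.021	52
IL7	3.59	1.21	4.35	1.39	0.023	53
LAP TGF-beta-1	7.53	0.67	8.00	0.88	0.023	54
TNFSF13	8.39	0.39	8.65	0.47	0.025	55
VIM	3.47	1.32	4.07	1.01	0.025	56
IL-12B	4.38	0.70	4.80	0.77	0.027	57
SEZ6L	5.33	0.40	5.06	0.51	0.027	58
hK11	5.79	0.77	6.35	1.07	0.027	59
SIRT2	3.38	1.99	4.66	2.46	0.028	60
EPHA2	1.46	0.46	1.79	0.64	0.028	61
4E-BP1	8.82	1.31	9.52	1.29	0.028	62
TNFRSF19	4.06	0.49	4.46	0.77	0.028	63
FURIN	4.02	0.46	4.29	0.50	0.029	64
CCL4	6.44	0.60	6.91	0.93	0.029	65
FADD	0.75	1.22	1.52	1.51	0.029	66
AXIN1	3.55	2.20	5.03	2.93	0.029	67
MCP-4	3.74	1.10	4.31	1.08	0.029	68
CEACAM1	7.56	0.17	7.43	0.23	0.029	69
CD27	7.85	0.43	8.14	0.58	0.029	70
HGF	8.39	0.54	8.78	0.79	0.031	71
FGF-21	5.82	1.52	6.69	1.72	0.034	72
STAMPB	4.90	1.67	5.96	2.15	0.034	73
MetAP 2	4.18	1.06	4.79	1.25	0.035	74
CASP-8	1.19	0.76	1.69	1.04	0.038	75
TNFB	3.92	0.39	3.60	0.72	0.043	76
CCL20	5.59	1.22	6.19	1.28	0.049	77
ST1A1	1.16	1.29	1.94	1.69	0.049	78
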