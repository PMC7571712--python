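protein	auc	ci_low	ci_high	rank
WFDC2	0.767	0.672	0.861	1
VEGFR-2	0.743	0.639	0.848	2
DNER	0.741	0.650	0.833	3
ITGAV	0.731	0.639	0.822	4
MUC-16	0.730	0.628	0.833	5
IL6	0.724	0.619	0.829	6
CXCL13	0.721	0.615	0.828	7
WISP-1	0.720	0.625	0.814	8
FR-alpha	0.719	0.632	0.805	9
MMP-1	0.710	0.610	0.810	10
MK	0.709	0.608	0.810	11
IL10	0.707	0.613	0.801	12
SCF	0.707	0.605	0.809	13
TNFRSF6B	0.706	0.605	0.807	14
CTSV	0.702	0.597	0.807	15
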