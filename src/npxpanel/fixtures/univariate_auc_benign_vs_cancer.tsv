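protein	auc	ci_low	ci_high	rank
WFDC2	0.830	0.739	0.921	1
FR-alpha	0.790	0.709	0.870	2
DNER	0.776	0.687	0.866	3
MUC-16	0.774	0.676	0.872	4
IL6	0.770	0.664	0.876	5
MK	0.765	0.666	0.863	6
VEGFR-2	0.764	0.661	0.867	7
IL10	0.763	0.670	0.855	8
ITGAV	0.761	0.673	0.849	9
WISP-1	0.757	0.665	0.849	10
TNFRSF6B	0.747	0.648	0.845	11
SCF	0.747	0.646	0.847	12
CXCL13	0.744	0.640	0.849	13
CDCP1	0.743	0.647	0.839	14
RSPO3	0.728	0.622	0.833	15
ABL1	0.726	0.625	0.827	16
CCL23	0.726	0.616	0.835	17
CXCL6	0.726	0.611	0.840	18
MMP-1	0.723	0.624	0.822	19
CXCL11	0.722	0.619	0.826	20
CTSV	0.722	0.620	0.825	21
CD40	0.719	0.617	0.821	22
VEGFA	0.718	0.617	0.819	23
CXCL9	0.716	0.603	0.829	24
CXCL1	0.713	0.602	0.825	25
TFPI-2	0.712	0.607	0.817	26
CSF-1	0.710	0.598	0.823	27
CCL3	0.710	0.603	0.817	28
TNFB	0.710	0.610	0.810	29
TNFRSF4	0.708	0.609	0.807	30
SCAMP3	0.706	0.606	0.807	31
TNFSF14	0.705	0.606	0.804	32
PVRL4	0.704	0.609	0.799	33
IL-10RB	0.703	0.602	0.803	34
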