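domain_order	functional	type	modification	occurrence
C-A-PCP	N	NRPS	L	1429
KS-AT-DH-KR-ACP	N	PKS	Enoyl	895
KS-AT-KR-ACP	N	PKS	Hydroxyl	628
C-A-PCP-E	N	NRPS	E	362
KS-AT-DH-ER-KR-ACP	N	PKS	Alkyl	335
KS-AT-ACP	N	PKS	Ketone	247
A-PCP	N	NRPS	L	235
C-A-PCP-TE	N	NRPS	L	202
KS-tAT_d-KR-ACP	S	PKS	Hydroxyl	139
KS-tAT_d-DH-KR-ACP	S	PKS	Enoyl	125
C-A-nMT-PCP	N	NRPS	L	120
KS-tAT_d-ACP	S	PKS	Alkyl	71
cAL-ACP	NF	PKS	-	62
KS-AT-DH-KR-ACP-TE	N	PKS	Enoyl	61
C-A-ACP	N	Mixed	L	61
C-PCP	NF	NRPS	-	59
KS-ACP	S	PKS	Ketone	52
KS-tAT_d	S	PKS	Ketone	52
KS-AT	S	PKS	Ketone	49
KS-tAT_d-DH-KR-cMT-ACP	S	PKS	Enoyl	49
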