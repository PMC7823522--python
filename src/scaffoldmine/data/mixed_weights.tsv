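cluster_type	similarity	mcs	psm
PKS	1	1	0.3
NRPS	1	0.4	0.5
Mixed	0.4	0.6	0.1
All	0.3	0.4	0.1
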