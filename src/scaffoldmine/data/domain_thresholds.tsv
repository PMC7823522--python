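domain	name	domT
ACP	Acyl carrier protein	13.9
AT	Acyltransferase	47.4
A	Adenylation domain	19.6
CAL	Coenzyme A ligase	221.8
C	Condensation domain	25.9
DH2	Dehydratase	33.2
DH	Dehydratase	31.1
DHt	Dehydratase	44.3
ER	Enoylreductase	68.8
E	Epimerization domain	60.4
KR	Ketoreductase	20
KS	Keto-synthase	72
PCP	Peptide carrier protein	21.9
TD	Reductive Thioesterase	42.1
TE	Thioesterase	36.5
bACP	beta-branching acyl carrier protein	28.9
cMT	C-Methyltransferase	104.7
nMT	N-Methyltransferase	42.7
oMT	O-Methyltransferase	70.6
tAT_d	Trans-acyltransferase docking domain	50
KSQ	Decarboxylating keto-synthase	72
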