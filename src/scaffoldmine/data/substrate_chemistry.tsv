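label	kind	side_chain	template
malonyl	PK
methylmalonyl	PK	C
ethylmalonyl	PK	CC
methoxymalonyl	PK	OC
A	NRP	C
C	NRP	CS
D	NRP	CC(=O)O
E	NRP	CCC(=O)O
F	NRP	Cc1ccccc1
G	NRP
H	NRP	Cc1c[nH]cn1
I	NRP	C(C)CC
K	NRP	CCCCN
L	NRP	CC(C)C
N	NRP	CC(N)=O
P	NRP		N1CCCC1
Q	NRP	CCC(N)=O
R	NRP	CCCNC(=N)N
S	NRP	CO
T	NRP	C(C)O
V	NRP	C(C)C
W	NRP	Cc1c[nH]c2ccccc12
Y	NRP	Cc1ccc(O)cc1
aad	NRP	CCCC(=O)O
bht	NRP	C(O)c1ccc(O)cc1
dab	NRP	CCN
dhb	NRP		c1cccc(O)c1O
dhbu	NRP		NC(=CC)
dhpg	NRP	c1cc(O)cc(O)c1
horn	NRP	CCCNO
hpg	NRP	c1ccc(O)cc1
orn	NRP	CCCN
pip	NRP		N1CCCCC1
gly	NRP
ala	NRP	C
val	NRP	C(C)C
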