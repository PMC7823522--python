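name	smarts
Glyco	[#6]O[D3]1CCCCO1
Cl	Cl
Spiroketal	[C&R]O[C&R]([C&R])([C&R])O[C&R]
SS	SS
NO2	O=[N+][O-]
6-Ring	CC1CCCC(C)O1
5-Ring	C1CCCO1
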