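Sample	Sequence	Modifications	Proteins	Leading razor protein	MS/MS count
S1	AAAAAAK		DEER1	DEER1	3
S1	AAAAAK		DEER1	DEER1	1
S1	AKAKAKAK		DEER1	DEER1	1
S1	GGGGGGK		KERA1	KERA1	2
S1	DDDDDDK		DEER1	DEER1	2
S1	EEEEEEK		DEER2	DEER2	1
S1	FFFFFFK		SALM1	SALM1	1
S1	IIIIIIK		DEER2	DEER2	2
S1	SSSSSSK		DEER1	DEER1	1
S2	FFFFFFK		SALM1	SALM1	2
S2	HHHHHHK		SALM1	SALM1	1
S2	MMMMMMK		DEER1;SALM1	SALM1	1
S2	GGGGGGK		KERA1	KERA1	1
S2	NNNNNNK	Deamidation (NQ)@2	SALM1	SALM1	1
S2	PPPPPPK		SALM2	SALM2	5
S2	QQQQQK		SALM1	SALM1	1
S2	WWWWWWK		UNK1	UNK1	1
S2	YYYYYYR		KERA1	KERA1	1
W1	DDDDDDK		DEER1	DEER1	1
W2	HHHHHHK		SALM1	SALM1	1
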