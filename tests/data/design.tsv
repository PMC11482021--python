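sample_id	ingredient	matrix	burial	replicate	cofire_group	run_order
W1		wash	unburied	0		1
S1	S_deer	foodcrust	unburied	1	g1	2
W2		wash	unburied	0		3
S2	S_salmon	foodcrust	unburied	1	g1	4
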