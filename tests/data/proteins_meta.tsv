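accession	taxon_id	category
DEER1	S_deer	target
DEER2	S_deer	target
SALM1	S_salmon	target
SALM2	S_salmon	target
KERA1	S_contam	contaminant
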