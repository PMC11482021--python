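taxon_id	parent_id	name	rank
root	root	cellular organisms	root
K_anim	root	Animalia	kingdom
F_cerv	K_anim	Cervidae	family
S_deer	F_cerv	red deer	species
F_salmo	K_anim	Salmonidae	family
S_salmon	F_salmo	Atlantic salmon	species
K_cont	root	laboratory contaminants	kingdom
S_contam	K_cont	human keratin source	species
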