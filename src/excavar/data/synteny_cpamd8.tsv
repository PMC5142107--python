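species	lineage	left_flank	gene_present	right_flank
human	primate	HAUS8	1	SIN3B
chimpanzee	primate	HAUS8	1	SIN3B
macaque	primate	HAUS8	1	SIN3B
dog	carnivore	HAUS8	1	SIN3B
cow	artiodactyl	HAUS8	1	SIN3B
opossum	marsupial	HAUS8	1	SIN3B
chicken	bird	HAUS8	1	SIN3B
xenopus	amphibian	HAUS8	1	SIN3B
zebrafish	fish	HAUS8	1	SIN3B
mouse	rodent	HAUS8	0	SIN3B
rat	rodent	HAUS8	0	SIN3B
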