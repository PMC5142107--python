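# Genes previously associated with anterior segment dysgenesis
FOXC1
PITX2
PAX6
PITX3
FOXE3
BMP4
CHRDL1
LTBP2
CYP1B1
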