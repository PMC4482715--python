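name,recognition,cut_offset_top
BslI,CCNNNNNNNGG,7
EcoRI,GAATTC,1
EcoRV,GATATC,3
HindIII,AAGCTT,1
BamHI,GGATCC,1
XhoI,CTCGAG,1
SmaI,CCCGGG,3
AluI,AGCT,2
DraI,TTTAAA,3
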