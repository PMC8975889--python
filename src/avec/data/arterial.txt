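Bmx
Cxcr4
Dll4
Efnb2
Epas1
Gja4
Gja5
Hey1
Igfbp3
Mecom
Nrp1
Unc5b
Vegfc
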