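Aplnr
Nr2f2
Nrp2
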