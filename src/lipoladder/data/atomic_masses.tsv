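# monoisotopic atomic masses, Da (table version 1)
symbol	mass
H	1.0078250319
C	12.0000000000
N	14.0030740052
O	15.9949146221
S	31.9720706900
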