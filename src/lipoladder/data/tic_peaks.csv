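# Six-member lipopeptide isoform family: total-ion-chromatogram peaks
# (retention-time and protonated-mass means over 3 injections; intensities
# were not recorded and are placeholders — the annotator never uses them).
rt_min,mz,intensity,id
23.67,994.6701,1.0,A
24.50,1008.6832,1.0,B
25.85,1022.6963,1.0,C
26.56,1036.7073,1.0,D
22.70,1040.7147,1.0,CL
23.39,1054.7286,1.0,DL
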