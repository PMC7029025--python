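# Antimicrobial activity of the four cyclic isoforms (mean ± SD of triplicates).
# zone_note: the fungal inhibition-zone column was recorded as "radius (mm)" in
# the source assay sheet while the bacterial one is a diameter; numbers are
# stored verbatim, unconverted.
designation,tail_carbons,organism_class,zone_mm_mean,zone_mm_sd,mic_mean,mic_sd,zone_note
A,12,bacteria,18.33,1.52,3.16,0.763,diameter
B,13,bacteria,13.16,1.6,5.83,0.28,diameter
C,14,bacteria,11,1.73,7.33,0.57,diameter
D,15,bacteria,8.23,1.53,10.5,0.5,diameter
A,12,fungi,1.83,0.29,12.5,0.86,radius_as_recorded
B,13,fungi,2.33,0.57,9.56,0.58,radius_as_recorded
C,14,fungi,4.76,0.93,5.73,0.68,radius_as_recorded
D,15,fungi,5.5,0.86,4.4,0.36,radius_as_recorded
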