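# Conversion between vendor-style "lipid tail formula" labels (the Biolynx
# post-translational-modification convention used in de novo sequencing
# software) and this package's bookkeeping, where the tail is the free
# saturated beta-hydroxy fatty acid CnH2nO3 and every condensation is an
# explicit water loss.  (table version 1)
label	tail_carbons	topology
C12H22O4	12	cyclic
C13H24O4	13	cyclic
C14H26O4	14	cyclic
C15H28O4	15	cyclic
C14H27O4	14	linear
C15H29O4	15	linear
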