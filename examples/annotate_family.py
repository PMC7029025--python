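"""Annotate the bundled six-peak reference list into an isoform family.

The input is a centroided MS1 peak list (retention time, m/z, intensity).
The pipeline links peaks differing by one CH2 (14.016 Da, one more tail
carbon) or one water (18.011 Da, lactone hydrolysed to the linear form),
propagates tail carbon counts from the single member whose tail length is
known independently (the C13 member, id "B"), and letters the family.
"""

import lipoladder as lp

peaks = lp.bundled_peaklist()
(family,) = lp.annotate_peaks(peaks, anchor=("B", 13))

print(f"{'designation':>12} {'rt/min':>7} {'m/z':>10} {'topology':>9} "
      f"{'tail':>5} {'offset/Da':>9}")
for m in family.members:
    print(f"{m.designation:>12} {m.peak.rt:7.2f} {m.peak.mz:10.4f} "
          f"{m.topology:>9} {'C' + str(m.tail_carbons):>5} {m.nominal_offset:9d}")

print("\nladder edges (light -> heavy):")
for e in family.edges:
    print(f"  {e.from_peak:>3} -> {e.to_peak:<3} {e.kind:5} "
          f"delta {e.observed_delta:7.4f} Da (off canonical by {e.residual:.4f})")

# Four cyclic homologs A-D span tails C12-C15 (offsets 0/14/28/42 Da from the
# lightest); C_L and D_L are the water-added linear forms of C and D, eluting
# ~3 min earlier because their free carboxyl/hydroxyl make them more polar.
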