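"""Generate a synthetic isoform family and measure planted-truth recovery.

The generator plants a six-member family (cyclic C12-C15 plus linear C14/C15)
with 0.015 Da mass scatter and 50 contaminant peaks, then the annotator is
asked to find it again. Ground truth ships with every synthetic peak, so
recovery is scored exactly.
"""

import lipoladder as lp

config = lp.SimulationConfig(mass_sd=0.015, noise_peaks=50, seed=11)
peaks, truth = lp.simulate_family(config)
print(f"simulated {len(peaks)} peaks ({config.noise_peaks} of them noise)")

anchor = next(r for r in truth if r.designation == "B")
families = lp.annotate_peaks(peaks, anchor=(anchor.peak_id, anchor.tail_carbons))
main_family = families[0]  # families are sorted largest first
print(f"largest recovered family has {len(main_family)} members:")

truth_by_id = {r.peak_id: r for r in truth}
correct = 0
for m in main_family.members:
    planted = truth_by_id[m.peak.id]
    ok = (m.designation, m.topology, m.tail_carbons) == (
        planted.designation, planted.topology, planted.tail_carbons
    )
    correct += ok
    print(f"  {m.peak.id:>4} called {m.designation:>4}/{m.topology:<7} "
          f"C{m.tail_carbons}  planted {planted.designation:>4}/{planted.topology:<7}"
          f" {'ok' if ok else 'MISS'}")
print(f"{correct}/{len(main_family)} members fully correct")
# With 0.015 Da scatter an occasional edge falls outside the 0.03 Da
# tolerance and a member drops off the family; the truth table makes such
# misses visible instead of silent.
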