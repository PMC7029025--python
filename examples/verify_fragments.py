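"""Verify a composition hypothesis against a fragment (MS2) spectrum.

Generates the theoretical b/y ion ladder for a C12-tail heptapeptide, builds
a synthetic spectrum from it, matches spectrum to theory, and runs the
ring-opening topology test: a cyclic depsipeptide yields a daughter ion one
water ABOVE its parent m/z when collision-induced dissociation opens the
lactone; a linear parent never does.
"""

import lipoladder as lp

spec = lp.LipopeptideSpec("LLLVDLL", tail_carbons=12, topology="cyclic")
parent = lp.protonated_mz(lp.assemble_neutral(spec))
print(f"cyclic C12 parent [M+H]+ = {parent:.4f}")
print(f"expected ring-opened daughter = {lp.ring_open(parent):.4f} (+18.0106)\n")

for ion in lp.fragment_table(spec):
    label = f"{ion.series}{ion.index}" if ion.index else ion.series
    print(f"  {label:>18} {ion.mz:10.4f}  {ion.composition_note}")

spectrum = lp.simulate_ms2(spec, dropout=0.2, mz_jitter_sd=0.01, seed=7)
match = lp.match_spectrum(parent, spectrum, spec, frag_tol=0.05)
print(f"\nmatched {len(match.matched)} ions, b/y coverage {match.coverage:.2f}, "
      f"topology call: {match.topology_call}")
# Coverage is the matched fraction of the 12 b/y positions; the cyclic call
# comes from the daughter ion at parent + 18 Da, independent of coverage.
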