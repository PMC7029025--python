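"""Rank candidate compositions against an observed protonated mass.

Mass spectra alone cannot always pin a sequence: here an observed family
member at m/z 994.6701 is compared against two heptapeptide hypotheses with
a C12 beta-hydroxy tail — all-leucine LLLVDLL and the surfactin-like ELLVDLL
(one glutamate). The ppm error of each theoretical [M+H]+ decides the
ranking; the 30 ppm window marks which fits are reportable matches.
"""

import lipoladder as lp

observed = 994.6701
candidates = [
    lp.LipopeptideSpec(seq, 12, "cyclic") for seq in ("LLLVDLL", "ELLVDLL")
]
for fit in lp.composition_fit(observed, candidates):
    flag = "MATCH" if fit.within else "  far"
    print(f"{fit.spec.sequence}  theo {fit.theoretical_mz:9.4f}  "
          f"delta {fit.delta:+8.4f} Da  {fit.ppm:+7.1f} ppm  [{flag}]")
# The one-Glu composition lands ~27 ppm from the observed mass; the pure-Leu
# one is ~16 Da (one oxygen) away. The package reports both and adjudicates
# neither — that is a chemistry question, not a mass-arithmetic one.
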