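# Methods

## Mass bookkeeping

All arithmetic is monoisotopic, over the element set {C, H, N, O, S} with
atomic masses pinned in `src/lipoladder/data/atomic_masses.tsv`
(H 1.0078250319, C 12 exactly, N 14.0030740052, O 15.9949146221,
S 31.97207069; proton 1.00727646 Da). The instrument context is a Q-TOF
reporting singly protonated monoisotopic centroids, so average masses,
charge states above 1, adducts other than [M+H]⁺ and isotope envelopes are
all out of scope by design.

The fatty-acid tail is always represented as the free saturated β-hydroxy
acid CnH2nO3, and every condensation is an explicit water loss: the amide
bond to the N-terminal residue costs one water (cancelling the water the
free termini would otherwise add, so M_linear = Σresidues + tail), and the
lactone closing the depsipeptide ring costs one more (M_cyclic = M_linear −
H₂O). This makes two identities exact to machine precision, and the test
suite asserts them at 1e-9 Da: linear − cyclic = 18.0105646 Da for any
composition, and +1 tail carbon = +14.0156500 Da. Vendor sequencing software
instead folds an unstated number of waters into printed "lipid tail
formulas" (C12H22O4 and the like); those labels are accepted as input via a
shipped conversion table (`tail_label_to_spec`) but never used internally,
precisely because their water bookkeeping is not self-describing.

Residue masses derive from per-residue formulas in
`data/residue_masses.tsv`; load-time validation rejects any stored mass more
than 1e-6 Da from its own formula. Leucine and isoleucine are isobaric and
CID cannot tell them apart; sequences are written with L by convention and
no disambiguation is attempted. An unsaturated tail (one C=C) is modelled as
−2 H; branching is mass-silent and not represented.

## Ladder detection and family assembly

Candidate edges join peak pairs whose m/z difference lies within tolerance
of one methylene (CH2 edge) or one water (WATER edge). Defaults are
`ch2_tol = water_tol = 0.03 Da`: per-peak injection scatter on the target
instrument class is 0.01–0.02 Da, so pairwise deltas of true partners sit
within ~0.01 Da of canonical, well inside 0.03, while the 1 Da isotope grid
and unrelated peaks are far outside. Both tolerances are exposed in
configuration because no universal value exists — they are an instrument
property.

When two candidate partners compete for the same ladder slot (same peak,
same edge kind, same direction), the edge with the smaller mass residual
wins; ties break by smaller retention-time gap, then lexicographic peak ids,
so the output is fully deterministic and invariant under permutation of the
input (a property test shuffles and re-runs). Connected components become
families; singletons are reported as one-member families rather than
errors, since real peak lists contain contaminants. Families are ordered
largest-first, then by lightest member.

Topology is called per water edge — heavier member linear, lighter cyclic —
because hydrolysis adds mass. Retention order (linear forms eluting earlier
than their cyclic partners; mass increasing with elution within a topology
class on reverse phase) is corroborating evidence only: violations append
warnings and never delete an edge, since retention behaviour is gradient-
dependent. CH2-connected peaks without a water edge default to cyclic (the
majority class of a homolog chain); isolated peaks stay `unknown`.

Tail carbon counts cannot be read off absolute masses when the head-group
composition is itself uncertain (see "Composition ranking" below), so they
are propagated relationally from a single anchor — one member whose tail
length is known from prior characterisation — by breadth-first search: +1
carbon toward the heavier member of a CH2 edge, unchanged across a water
edge. If two paths disagree, the propagation raises an error naming the peak
instead of guessing; this can only happen when tolerances are set wide
enough that one gap reads as both edge kinds. Nominal integer offsets from
the lightest cyclic member (0/14/28/42 Da for a four-member series) are
reported because that is how family tables are conventionally printed.

## Fragment model and topology test

Only singly charged b and y ions are generated — the interpretive practice
this pipeline encodes uses b/y ladders exclusively — with the acyl
modification (tail minus one water) on the b side. A cyclic spec is
ring-opened at the ester before series generation, so its b/y table equals
its linear counterpart's plus the ring-opened parent ion; ring opening is
modelled only at the lactone because amide-opened linearisation adds no
water and is invisible in the parent region. Spectrum matching is greedy by
smallest |Δm| with each observed peak used at most once (`frag_tol` default
0.05 Da, Q-TOF fragment accuracy); coverage counts matched b/y positions
only. The topology test asks whether any fragment lies within
`daughter_tol` of parent + 18.0105646 Da: present → cyclic, absent with a
non-empty spectrum → linear, empty spectrum → inconclusive. `daughter_tol`
defaults to a deliberately wide 0.2 Da: the daughter sits on the shoulder of
an intense parent where centroiding can displace it by ~0.1 Da, and a tight
window would reject genuine ring-opened daughters. When MS1 (water-partner)
and MS2 (daughter-ion) calls conflict, the MS2 call wins with a recorded
note — fragmentation interrogates the molecule directly, the MS1 call only
its neighbourhood.

## Composition ranking

`composition_fit` ranks candidate (sequence, tail, topology) hypotheses by
|ppm| against an observed m/z, tie-broken deterministically. The default
reporting window is 30 ppm. That is wide for a Q-TOF, and deliberately so:
for the reference family bundled here, the best chemically sensible
composition (the surfactin-like one-glutamate variant of the all-leucine
heptapeptide) sits ~27 ppm from the printed mean, while the all-leucine
composition is one oxygen (~16 Da) away. The package computes and reports
both fits and adjudicates neither; resolving the head group is a chemistry
question outside what mass arithmetic can decide.

## Synthetic data

`simulate_family` emulates exactly the statistical structure the detector
assumes: member [M+H]⁺ values assembled from the composition model
(optionally shifted rigidly by `sequence_hypothesis_mass_offset`, which lets
a fixture plant peaks at externally printed masses without asserting a
composition), i.i.d. Gaussian mass scatter per peak (default SD 0.015 Da,
the middle of the observed injection-scatter range), retention times linear
in tail carbons (0.9 min/carbon on a 12.9 min intercept, matching the
roughly one-minute homolog spacing; linear forms 3.1 min earlier), 0.1 min
RT jitter, log-uniform intensities, and uniform contaminant peaks. Defaults
describe the six-member reference condition: cyclic C12–C15 with linear
partners for C14 and C15. Same seed ⇒ byte-identical output.

It does **not** emulate chromatographic peak shape, isotope envelopes,
charge states, adducts, intensity-dependent mass error, or correlated
(calibration-drift) mass error. The last omission matters for interpreting
recovery numbers: with i.i.d. per-peak noise, the error of a pairwise delta
is √2 larger than the per-peak SD, which is the pessimistic extreme — on a
real instrument much of the scatter is shared calibration error that
cancels in deltas. Passing recovery tests on this generator therefore says
the detector handles worst-case uncorrelated scatter; real family data
should behave better, but that is an extrapolation, not a tested fact.

**Recovery metrics.** Noiseless recovery is exact equality of membership,
topology, designation and tail count with the planted truth. Under mass
noise, *member-level recovery* is defined as: a planted member is recovered
when the detector places it in a family with at least one of its true
homolog partners (its linkage is found). The stricter alternative —
connectivity to the anchor through surviving edges — conflates one member's
scatter with its neighbours' and has closed-form expectation ≈ 0.84 at
SD 0.015 / tolerance 0.03 (per-edge survival P(|N(0, 0.015√2)| ≤ 0.03) ≈
0.843, and an end member has exactly one possible edge). Even the
member-level metric falls short of naive independence arithmetic (≈ 0.956)
because the two edges incident on one peak share that peak's mass error and
fail together: the measured value over 200 seeded families is ≈ 0.94. Raising
tolerances toward 0.05 Da would lift per-edge survival to ≈ 0.98, at the cost
of admitting more contaminant edges; the 0.03 Da default keeps the
specificity-leaning choice.

## Structure–activity analysis

The potency question is ordinal (does activity rise or fall with tail
length over four isoforms?), so the trend statistic is Spearman's rank
correlation of tail carbons against the response mean; with n = 4 no
linearity claim is defensible and Pearson would overreach. |ρ| < 0.5 is
reported as "flat"; a constant response leaves ranks undefined and raises.
The selectivity index is MIC(fungi)/MIC(bacteria) per isoform (> 1 =
bacteria-selective), with the crossover reported as the adjacent tail-length
pair whose ratios bracket 1. Because the source assays report only means ±
SD of triplicates, uncertainty is propagated by parametric bootstrap:
resample each mean from N(mean, SD), recompute ρ, report the fraction of
resamples preserving its sign. Normal resampling is the only model the
available summaries support; it can produce non-physical negative MIC draws
in extreme tails, which is harmless for a rank statistic. Linear isoforms
carry no activity data and the module makes no claim about them.

The bundled activity fixture stores the assay numbers verbatim; note that
its fungal inhibition-zone column was recorded as a radius in the source
assay sheet while the bacterial one is a diameter, so the two zone columns
are not directly comparable to each other (MICs are, and all trend
conclusions rest on within-column ordering, which unit conventions cannot
affect).

## Numerical and interface choices

* Exact identities (water split, methylene rung, b_i + y_{n−i} = [M+H]⁺ +
  proton) are tested at 1e-9 Da; hand-derived example values at 5e-4 Da
  (they were derived with 5-decimal residue masses).
* All retention times are minutes; all m/z are singly protonated values.
* Reports are JSON (full evidence trail: edges, residuals, warnings,
  per-member evidence strings) plus a flat CSV with the conventional family-
  table columns; reruns are byte-identical.
* Peak ids default to row indices when the CSV has no id column; duplicate
  ids are rejected.
* Problem sizes in the test suite (100 noiseless + 200 noisy simulated
  families, 100-spec property sweeps, 1000-draw bootstraps) were chosen so
  the whole suite runs in seconds while estimator standard errors stay an
  order of magnitude below the margins being asserted.

## Known limitations

* No peak picking: input must already be a centroided peak list.
* No de novo sequencing: candidate sequences are verified, not enumerated.
* Tail-length inference needs one anchored member; absolute inference from
  mass alone is impossible while the head-group composition is open.
* The CH2/water tolerance is a per-instrument setting; the defaults encode
  one instrument class, not a universal truth.
* Stereochemistry (β-hydroxy R/S) and Leu/Ile identity are invisible to the
  method and deliberately unmodelled.
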