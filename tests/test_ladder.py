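"""MS1 ladder detection, topology calls, tail propagation, designations."""

import random

import pytest

import lipoladder as lp
from lipoladder.ladder import (
    IsoformFamily,
    ObservedPeak,
    assign_designations,
    classify_topology_ms1,
    detect_ladders,
    infer_tail_lengths,
)


def _edge_set(family):
    return {(e.from_peak, e.to_peak, e.kind) for e in family.edges}


class TestDetectLadders:
    def test_family_fixture_gives_one_family_of_six(self, family_peaks):
        families = detect_ladders(family_peaks)
        assert len(families) == 1
        assert len(families[0]) == 6
        assert _edge_set(families[0]) == {
            ("A", "B", "CH2"),
            ("B", "C", "CH2"),
            ("C", "D", "CH2"),
            ("CL", "DL", "CH2"),
            ("C", "CL", "WATER"),
            ("D", "DL", "WATER"),
        }

    def test_edge_residuals_within_tolerance(self, family_peaks):
        (family,) = detect_ladders(family_peaks)
        for edge in family.edges:
            assert edge.residual <= {"CH2": 0.03, "WATER": 0.03}[edge.kind]

    def test_single_peak_is_singleton(self):
        families = detect_ladders([ObservedPeak("p", 1.0, 500.0, 1.0)])
        assert len(families) == 1 and len(families[0]) == 1 and not families[0].edges

    def test_unrelated_peaks_stay_separate(self):
        peaks = [ObservedPeak("a", 1.0, 500.0, 1.0), ObservedPeak("b", 2.0, 501.0, 1.0)]
        assert len(detect_ladders(peaks)) == 2

    def test_permutation_invariance(self, family_peaks):
        reference = detect_ladders(family_peaks)
        rng = random.Random(11)
        for _ in range(10):
            shuffled = family_peaks[:]
            rng.shuffle(shuffled)
            families = detect_ladders(shuffled)
            assert [_edge_set(f) for f in families] == [_edge_set(f) for f in reference]
            assert [[m.peak.id for m in f.members] for f in families] == [
                [m.peak.id for m in f.members] for f in reference
            ]

    def test_conflicting_partners_resolved_by_residual(self):
        # two candidates ~14 Da above the base peak; the closer one wins the slot
        peaks = [
            ObservedPeak("base", 10.0, 500.0, 1.0),
            ObservedPeak("good", 11.0, 514.016, 1.0),
            ObservedPeak("bad", 11.5, 514.030, 1.0),
        ]
        (family, singleton) = detect_ladders(peaks)
        assert _edge_set(family) == {("base", "good", "CH2")}
        assert singleton.members[0].peak.id == "bad"

    def test_rejects_bad_tolerance(self, family_peaks):
        with pytest.raises(ValueError):
            detect_ladders(family_peaks, ch2_tol=0.0)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            detect_ladders([])


class TestTopology:
    def test_family_fixture_calls(self, family_peaks):
        (family,) = detect_ladders(family_peaks)
        classify_topology_ms1(family)
        calls = {m.peak.id: m.topology for m in family.members}
        assert calls == {
            "A": "cyclic", "B": "cyclic", "C": "cyclic", "D": "cyclic",
            "CL": "linear", "DL": "linear",
        }
        assert family.warnings == []  # linear members elute ~3 min earlier

    def test_late_eluting_linear_candidate_warns(self):
        peaks = [
            ObservedPeak("cyc", 10.0, 1000.0, 1.0),
            ObservedPeak("lin", 12.0, 1018.0106, 1.0),  # heavier AND later
        ]
        (family,) = detect_ladders(peaks)
        classify_topology_ms1(family)
        assert family.member("lin").topology == "linear"
        assert any("elute earlier" in w for w in family.warnings)

    def test_pure_ch2_chain_defaults_cyclic(self):
        peaks = [
            ObservedPeak("a", 1.0, 1000.0, 1.0),
            ObservedPeak("b", 2.0, 1014.01565, 1.0),
        ]
        (family,) = detect_ladders(peaks)
        classify_topology_ms1(family)
        assert all(m.topology == "cyclic" for m in family.members)

    def test_isolated_peak_is_unknown(self):
        (family,) = detect_ladders([ObservedPeak("p", 1.0, 500.0, 1.0)])
        classify_topology_ms1(family)
        assert family.members[0].topology == "unknown"


class TestTailInference:
    def test_propagation_from_anchor(self, annotated_family):
        carbons = {m.peak.id: m.tail_carbons for m in annotated_family.members}
        assert carbons == {"A": 12, "B": 13, "C": 14, "D": 15, "CL": 14, "DL": 15}

    def test_nominal_offsets_from_lightest_cyclic(self, annotated_family):
        offsets = {
            m.peak.id: m.nominal_offset
            for m in annotated_family.members
            if m.topology == "cyclic"
        }
        assert offsets == {"A": 0, "B": 14, "C": 28, "D": 42}

    def test_water_edge_preserves_carbon_count(self, annotated_family):
        pairs = [("C", "CL"), ("D", "DL")]
        for cyclic_id, linear_id in pairs:
            assert (
                annotated_family.member(cyclic_id).tail_carbons
                == annotated_family.member(linear_id).tail_carbons
            )

    def test_single_member_family(self):
        (family,) = detect_ladders([ObservedPeak("p", 1.0, 500.0, 1.0)])
        classify_topology_ms1(family)
        infer_tail_lengths(family, ("p", 12))
        assert family.members[0].tail_carbons == 12

    def test_anchor_must_be_in_family(self, family_peaks):
        (family,) = detect_ladders(family_peaks)
        with pytest.raises(KeyError):
            infer_tail_lengths(family, ("nope", 13))

    def test_inconsistent_propagation_is_an_error(self):
        # with absurdly wide tolerances one 16 Da gap reads as BOTH a CH2 rung
        # (+1 carbon) and a water offset (+0): propagation must refuse, not guess
        peaks = [
            ObservedPeak("a", 1.0, 1000.0, 1.0),
            ObservedPeak("b", 2.0, 1016.0, 1.0),
        ]
        (family,) = detect_ladders(peaks, ch2_tol=2.0, water_tol=2.1)
        assert {e.kind for e in family.edges} == {"CH2", "WATER"}
        with pytest.raises(ValueError, match="inconsistent"):
            infer_tail_lengths(family, ("a", 12))


class TestDesignations:
    def test_family_fixture_designations(self, annotated_family):
        names = {m.peak.id: m.designation for m in annotated_family.members}
        assert names == {
            "A": "A", "B": "B", "C": "C", "D": "D", "CL": "C_L", "DL": "D_L",
        }

    def test_designation_order_follows_mass_order(self, annotated_family):
        cyclic = [m for m in annotated_family.members if m.topology == "cyclic"]
        by_mass = sorted(cyclic, key=lambda m: m.peak.mz)
        assert [m.designation for m in by_mass] == sorted(m.designation for m in cyclic)

    def test_lone_cyclic_member_is_A(self):
        (family,) = detect_ladders(
            [
                ObservedPeak("x", 1.0, 1000.0, 1.0),
                ObservedPeak("y", 2.0, 1014.0157, 1.0),
            ]
        )
        classify_topology_ms1(family)
        assign_designations(family)
        assert [m.designation for m in family.members] == ["A", "B"]

    def test_full_pipeline_permutation_invariant(self, family_peaks):
        reference = lp.annotate_peaks(family_peaks, anchor=("B", 13))
        rng = random.Random(5)
        for _ in range(5):
            shuffled = family_peaks[:]
            rng.shuffle(shuffled)
            families = lp.annotate_peaks(shuffled, anchor=("B", 13))
            assert [
                (m.peak.id, m.designation, m.topology, m.tail_carbons)
                for f in families
                for m in f.members
            ] == [
                (m.peak.id, m.designation, m.topology, m.tail_carbons)
                for f in reference
                for m in f.members
            ]
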