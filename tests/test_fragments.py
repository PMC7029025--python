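"""b/y fragment generation, spectrum matching, ring-opening topology test."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipoladder.chem import CONSTANTS
from lipoladder.fragments import (
    fragment_table,
    match_spectrum,
    reconcile_topology,
    ring_open,
    topology_test,
)
from lipoladder.model import LipopeptideSpec, assemble_neutral, protonated_mz

SPEC_C12_LINEAR = LipopeptideSpec("LLLVDLL", 12, "linear")

specs = st.builds(
    LipopeptideSpec,
    sequence=st.text(alphabet="GASPVTLINDQKEMHFRYW", min_size=2, max_size=10),
    tail_carbons=st.integers(3, 20),
    topology=st.sampled_from(["cyclic", "linear"]),
)


@pytest.mark.parametrize(
    "parent, expected",
    [(994.6701, 1012.6807), (0.0, 18.0105646), (1036.7073, 1054.7179)],
)
def test_ring_open(parent, expected):
    assert ring_open(parent) == pytest.approx(expected, abs=1e-4)


class TestFragmentTable:
    def test_known_b_and_y_ions(self):
        ions = {f"{i.series}{i.index}": i.mz for i in fragment_table(SPEC_C12_LINEAR)}
        assert ions["b2"] == pytest.approx(425.33738, abs=5e-4)
        assert ions["y2"] == pytest.approx(245.18596, abs=5e-4)

    def test_ion_count_is_2n_minus_2(self):
        assert len(fragment_table(SPEC_C12_LINEAR)) == 12

    def test_y_ions_are_tail_independent(self):
        short = fragment_table(LipopeptideSpec("LLLVDLL", 12, "linear"))
        long = fragment_table(LipopeptideSpec("LLLVDLL", 15, "linear"))
        y_short = sorted(i.mz for i in short if i.series == "y")
        y_long = sorted(i.mz for i in long if i.series == "y")
        assert y_short == pytest.approx(y_long, abs=1e-9)

    def test_cyclic_table_is_linear_table_plus_ring_opened_parent(self):
        cyclic_spec = LipopeptideSpec("LLLVDLL", 12, "cyclic")
        cyclic_ions = fragment_table(cyclic_spec)
        linear_ions = fragment_table(SPEC_C12_LINEAR)
        assert [i.mz for i in cyclic_ions[:-1]] == pytest.approx(
            [i.mz for i in linear_ions], abs=1e-9
        )
        extra = cyclic_ions[-1]
        assert extra.series == "ring_opened_parent"
        parent = protonated_mz(assemble_neutral(cyclic_spec))
        assert extra.mz == pytest.approx(ring_open(parent), abs=1e-9)

    def test_requires_two_residues(self):
        with pytest.raises(ValueError):
            fragment_table(LipopeptideSpec("L", 12, "linear"))

    @given(spec=specs)
    @settings(max_examples=100, derandomize=True)
    def test_by_complementarity(self, spec):
        """b_i + y_(n-i) = [M+H]+ of the linear form + one proton, exactly."""
        linear = LipopeptideSpec(spec.sequence, spec.tail_carbons, "linear", spec.tail_saturated)
        ions = fragment_table(linear)
        b = {i.index: i.mz for i in ions if i.series == "b"}
        y = {i.index: i.mz for i in ions if i.series == "y"}
        target = protonated_mz(assemble_neutral(linear)) + CONSTANTS.proton
        n = len(spec.sequence)
        for i in range(1, n):
            assert b[i] + y[n - i] == pytest.approx(target, abs=1e-9)


class TestMatchSpectrum:
    def _theoretical_spectrum(self, spec):
        return [(ion.mz, 100.0) for ion in fragment_table(spec)]

    def test_self_match_full_coverage(self):
        spectrum = self._theoretical_spectrum(SPEC_C12_LINEAR)
        parent = protonated_mz(assemble_neutral(SPEC_C12_LINEAR))
        match = match_spectrum(parent, spectrum, SPEC_C12_LINEAR)
        assert match.coverage == 1.0
        assert all(delta == 0 for _, _, delta in match.matched)

    def test_shifted_spectrum_matches_nothing(self):
        spectrum = [(mz + 0.5, i) for mz, i in self._theoretical_spectrum(SPEC_C12_LINEAR)]
        match = match_spectrum(1000.0, spectrum, SPEC_C12_LINEAR, frag_tol=0.2)
        assert match.coverage == 0.0

    def test_half_spectrum_half_coverage(self):
        spectrum = self._theoretical_spectrum(SPEC_C12_LINEAR)[:6]
        match = match_spectrum(1000.0, spectrum, SPEC_C12_LINEAR)
        assert match.coverage == 0.5

    def test_empty_spectrum_is_not_an_error(self):
        match = match_spectrum(1000.0, [], SPEC_C12_LINEAR)
        assert match.coverage == 0.0 and match.topology_call == "inconclusive"

    def test_each_observed_peak_used_once(self):
        # one observed peak between b1 and nothing else: at most one match
        ions = fragment_table(SPEC_C12_LINEAR)
        spectrum = [(ions[0].mz + 0.01, 50.0)]
        match = match_spectrum(1000.0, spectrum, SPEC_C12_LINEAR)
        assert len(match.matched) == 1

    def test_coverage_monotone_in_tolerance(self):
        spectrum = [(mz + 0.04, i) for mz, i in self._theoretical_spectrum(SPEC_C12_LINEAR)]
        coverages = [
            match_spectrum(1000.0, spectrum, SPEC_C12_LINEAR, frag_tol=tol).coverage
            for tol in (0.01, 0.05, 0.1)
        ]
        assert coverages == sorted(coverages)


class TestTopologyTest:
    def test_ring_opened_daughter_near_parent_calls_cyclic(self):
        # a daughter 18.12 Da above the parent still classifies cyclic within
        # the 0.2 Da daughter window
        assert topology_test(994.67, [(1012.79, 10.0)], daughter_tol=0.2) == "cyclic"

    def test_pure_by_spectrum_calls_linear(self):
        spec = LipopeptideSpec("LLLVDLL", 14, "linear")
        spectrum = [(ion.mz, 10.0) for ion in fragment_table(spec)]
        assert topology_test(1040.7147, spectrum) == "linear"

    def test_empty_spectrum_inconclusive(self):
        assert topology_test(994.67, []) == "inconclusive"

    def test_rejects_bad_tolerance(self):
        with pytest.raises(ValueError):
            topology_test(994.67, [(1012.79, 1.0)], daughter_tol=0.0)


@pytest.mark.parametrize(
    "ms1, ms2, expected",
    [
        ("cyclic", "cyclic", "cyclic"),
        ("linear", "inconclusive", "linear"),
        ("cyclic", "linear", "linear"),  # MS2 overrides, with conflict note
        ("unknown", "cyclic", "cyclic"),
    ],
)
def test_reconcile_topology(ms1, ms2, expected):
    final, note = reconcile_topology(ms1, ms2)
    assert final == expected
    if ms1 not in (expected, "unknown") and ms2 != "inconclusive":
        assert "conflict" in note
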