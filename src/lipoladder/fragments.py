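"""Theoretical MS2 fragments and the +18 Da ring-opening topology test.

Collision-induced dissociation of an N-acylated peptide produces two ladders
of singly charged ions: b ions (N-terminal prefixes, carrying the fatty-acyl
modification) and y ions (C-terminal suffixes, never carrying it). A cyclic
depsipeptide must first open its lactone ring hydrolytically, which adds one
water: the diagnostic signature of a cyclic parent is therefore a daughter
ion 18.0105646 Da ABOVE the parent m/z, while a linear parent fragments
without any such excess mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .chem import CONSTANTS, DEFAULT_RESIDUE_TABLE, ResidueMassTable, mono_mass
from .model import LipopeptideSpec, assemble_neutral, protonated_mz, tail_formula

__all__ = [
    "DEFAULT_FRAG_TOL",
    "DEFAULT_DAUGHTER_TOL",
    "FragmentIon",
    "SpectrumMatch",
    "ring_open",
    "fragment_table",
    "match_spectrum",
    "topology_test",
    "reconcile_topology",
]

#: b/y matching tolerance in Da — Q-TOF-scale fragment accuracy.
DEFAULT_FRAG_TOL = 0.05
#: Tolerance for recognising the ring-opened daughter near the parent. Wide
#: (0.2 Da) on purpose: the daughter sits in the low-resolution neighbourhood
#: of an intense parent and its centroid can be pulled a tenth of a Da.
DEFAULT_DAUGHTER_TOL = 0.2


def ring_open(parent_mz: float) -> float:
    """m/z of the hydrolytically ring-opened daughter: parent + one water."""
    if parent_mz < 0:
        raise ValueError("parent m/z must be non-negative")
    return parent_mz + CONSTANTS.water


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b", "y" or "ring_opened_parent"
    index: int  # 1..n-1 for b/y; 0 for ring_opened_parent
    mz: float  # singly protonated
    composition_note: str = ""


@dataclass
class SpectrumMatch:
    """Result of matching a theoretical ion table against an observed spectrum."""

    parent_mz: float
    matched: list[tuple[FragmentIon, float, float]]  # (ion, observed mz, delta)
    coverage: float  # matched fraction of the 2(n-1) b/y positions
    topology_call: str  # cyclic | linear | inconclusive


def fragment_table(
    spec: LipopeptideSpec, table: ResidueMassTable | None = None
) -> list[FragmentIon]:
    """All theoretical singly charged b and y ions for a spec.

    A cyclic spec is ring-opened at the ester before series generation (its
    b/y ladder equals the linear counterpart's) and additionally contributes
    the ring-opened parent ion itself. For an n-residue sequence the b/y
    ladder has 2(n-1) ions:

        b_i = sum(residues 1..i) + (tail acyl = CnH2nO3 - H2O) + proton
        y_j = sum(residues n-j+1..n) + H2O + proton
    """
    table = table or DEFAULT_RESIDUE_TABLE
    n = len(spec.sequence)
    if n < 2:
        raise ValueError("fragmentation requires at least two residues")
    acyl = mono_mass(tail_formula(spec.tail_carbons, spec.tail_saturated)) - CONSTANTS.water
    ions = []
    prefix = 0.0
    for i, letter in enumerate(spec.sequence[:-1], start=1):
        prefix += table.mass(letter)
        ions.append(
            FragmentIon(
                "b", i, prefix + acyl + CONSTANTS.proton,
                composition_note=f"{spec.sequence[:i]} + C{spec.tail_carbons} acyl",
            )
        )
    suffix = 0.0
    for j, letter in enumerate(reversed(spec.sequence[1:]), start=1):
        suffix += table.mass(letter)
        ions.append(
            FragmentIon(
                "y", j, suffix + CONSTANTS.water + CONSTANTS.proton,
                composition_note=spec.sequence[n - j:],
            )
        )
    if spec.topology == "cyclic":
        parent = protonated_mz(assemble_neutral(spec, table))
        ions.append(
            FragmentIon(
                "ring_opened_parent", 0, ring_open(parent),
                composition_note="parent + H2O (lactone hydrolysis)",
            )
        )
    return ions


def match_spectrum(
    parent_mz: float,
    peaks: Iterable[tuple[float, float]],
    spec: LipopeptideSpec,
    frag_tol: float = DEFAULT_FRAG_TOL,
    table: ResidueMassTable | None = None,
) -> SpectrumMatch:
    """Greedy nearest-peak matching of the theoretical ion table to a spectrum.

    Candidate (ion, peak) pairs within ``frag_tol`` are accepted smallest
    |delta| first, each observed peak used at most once. Coverage counts the
    matched fraction of b/y positions only (the ring-opened parent, when
    present, is matched and reported but is a topology diagnostic, not
    sequence coverage). An empty spectrum gives coverage 0, no error.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    peaks = sorted(peaks, key=lambda p: (p[0], p[1]))
    ions = fragment_table(spec, table)
    candidates = []
    for ion_idx, ion in enumerate(ions):
        for peak_idx, (mz, _intensity) in enumerate(peaks):
            delta = mz - ion.mz
            if abs(delta) <= frag_tol:
                candidates.append((abs(delta), ion_idx, peak_idx, delta))
    candidates.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    matched = []
    for _absdelta, ion_idx, peak_idx, delta in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        matched.append((ions[ion_idx], peaks[peak_idx][0], delta))
    matched.sort(key=lambda m: m[0].mz)

    by_positions = sum(1 for ion in ions if ion.series in ("b", "y"))
    by_matched = sum(1 for ion, _, _ in matched if ion.series in ("b", "y"))
    coverage = by_matched / by_positions if by_positions else 0.0
    return SpectrumMatch(
        parent_mz=parent_mz,
        matched=matched,
        coverage=coverage,
        topology_call=topology_test(parent_mz, peaks),
    )


def topology_test(
    parent_mz: float,
    peaks: Iterable[tuple[float, float]],
    daughter_tol: float = DEFAULT_DAUGHTER_TOL,
) -> str:
    """Cyclic/linear call from the ring-opened daughter ion.

    ``cyclic`` if any fragment lies within ``daughter_tol`` of
    parent + 18.0105646 Da; ``linear`` if fragments exist but none does (the
    structure was already open); ``inconclusive`` on an empty spectrum.
    """
    if daughter_tol <= 0:
        raise ValueError("daughter_tol must be positive")
    peaks = list(peaks)
    if not peaks:
        return "inconclusive"
    target = ring_open(parent_mz)
    if any(abs(mz - target) <= daughter_tol for mz, _ in peaks):
        return "cyclic"
    return "linear"


def reconcile_topology(ms1_call: str, ms2_call: str) -> tuple[str, str]:
    """Merge the MS1 (water-partner) and MS2 (daughter-ion) topology evidence.

    Fragmentation evidence is the stronger of the two, so a conclusive MS2
    call wins on conflict (with a note recording it); an inconclusive MS2
    defers to MS1. Returns (final call, provenance note).
    """
    if ms2_call == "inconclusive":
        return ms1_call, "MS2 inconclusive; MS1 call retained"
    if ms1_call == ms2_call:
        return ms1_call, "MS1 and MS2 evidence agree"
    if ms1_call in ("unknown", "inconclusive"):
        return ms2_call, "MS1 uninformative; MS2 call adopted"
    return ms2_call, f"conflict: MS1 said {ms1_call}, MS2 said {ms2_call}; MS2 overrides"
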