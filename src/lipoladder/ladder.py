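"""CH2 homolog-ladder and water-partner detection in MS1 peak lists.

Members of a lipopeptide isoform family differ by CH2 rungs in the fatty-acid
tail (14.0156500 Da between adjacent homologs) or by hydrolysis state of the
lactone (a linear form is one water, 18.0105646 Da, heavier than its cyclic
partner). This module finds those mass relations in a centroided peak list,
groups connected peaks into families, classifies topology, propagates tail
carbon counts from an anchor, and assigns alphabetical designations:

* cyclic members get letters A, B, C, ... in order of ascending protonated
  mass;
* each linear member inherits its cyclic water-partner's letter with an "_L"
  subscript (e.g. C_L).

Retention-time behaviour (homologs eluting about one minute apart with mass,
linear forms a few minutes earlier than their cyclic partners on reverse
phase) is used as corroboration: violations produce warnings, never filters.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .chem import CONSTANTS

__all__ = [
    "DEFAULT_CH2_TOL",
    "DEFAULT_WATER_TOL",
    "ObservedPeak",
    "LadderEdge",
    "IsoformAssignment",
    "IsoformFamily",
    "detect_ladders",
    "classify_topology_ms1",
    "infer_tail_lengths",
    "assign_designations",
    "annotate_peaks",
]

#: Mass tolerances in Da for calling a pairwise delta a CH2 rung or a water
#: offset. Injection-to-injection scatter on a Q-TOF is 0.01-0.02 Da per
#: peak, so pairwise deltas of genuine partners deviate from canonical by
#: about 0.01 Da; 0.03 Da accepts those with margin while rejecting the
#: 1 Da isotope grid.
DEFAULT_CH2_TOL = 0.03
DEFAULT_WATER_TOL = 0.03


@dataclass(frozen=True)
class ObservedPeak:
    """One centroided MS1 peak: retention time (min), m/z (Da), intensity."""

    id: str
    rt: float
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"peak {self.id}: rt must be >= 0, got {self.rt}")
        if self.mz <= 0:
            raise ValueError(f"peak {self.id}: mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak {self.id}: intensity must be >= 0")


@dataclass(frozen=True)
class LadderEdge:
    """A mass relation between two peaks, oriented light -> heavy."""

    from_peak: str  # lighter member
    to_peak: str  # heavier member
    kind: str  # "CH2" or "WATER"
    observed_delta: float
    residual: float  # |observed_delta - canonical delta|


@dataclass
class IsoformAssignment:
    """Annotation attached to one peak of a family."""

    peak: ObservedPeak
    designation: str | None = None
    topology: str = "unknown"  # cyclic | linear | unknown
    tail_carbons: int | None = None
    nominal_offset: int | None = None  # round(mz - lightest cyclic mz), Da
    evidence: list[str] = field(default_factory=list)


@dataclass
class IsoformFamily:
    """A connected component of ladder edges plus its member annotations."""

    members: list[IsoformAssignment]
    edges: list[LadderEdge] = field(default_factory=list)
    anchor: tuple[str, int] | None = None
    warnings: list[str] = field(default_factory=list)

    def member(self, peak_id: str) -> IsoformAssignment:
        for m in self.members:
            if m.peak.id == peak_id:
                return m
        raise KeyError(f"peak {peak_id!r} not in family")

    def __contains__(self, peak_id: str) -> bool:
        return any(m.peak.id == peak_id for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


_CANONICAL = {"CH2": CONSTANTS.methylene, "WATER": CONSTANTS.water}


def _candidate_edges(
    peaks: Sequence[ObservedPeak], ch2_tol: float, water_tol: float
) -> list[LadderEdge]:
    tol = {"CH2": ch2_tol, "WATER": water_tol}
    edges = []
    for light, heavy in itertools.combinations(peaks, 2):
        delta = heavy.mz - light.mz
        for kind, canonical in _CANONICAL.items():
            residual = abs(delta - canonical)
            if residual <= tol[kind]:
                edges.append(LadderEdge(light.id, heavy.id, kind, delta, residual))
    return edges


def _resolve_conflicts(
    edges: list[LadderEdge], peaks_by_id: dict[str, ObservedPeak]
) -> list[LadderEdge]:
    # One peak may occupy each ladder slot (kind x direction) once; when two
    # candidate partners compete, keep the smaller mass residual, then the
    # smaller RT gap, then lexicographic ids (fully deterministic).
    def rt_gap(edge: LadderEdge) -> float:
        return abs(peaks_by_id[edge.to_peak].rt - peaks_by_id[edge.from_peak].rt)

    ranked = sorted(edges, key=lambda e: (e.residual, rt_gap(e), e.from_peak, e.to_peak))
    taken: set[tuple[str, str, str]] = set()
    kept = []
    for edge in ranked:
        slots = [(edge.from_peak, edge.kind, "up"), (edge.to_peak, edge.kind, "down")]
        if any(slot in taken for slot in slots):
            continue
        taken.update(slots)
        kept.append(edge)
    return kept


def detect_ladders(
    peaks: Iterable[ObservedPeak],
    ch2_tol: float = DEFAULT_CH2_TOL,
    water_tol: float = DEFAULT_WATER_TOL,
) -> list[IsoformFamily]:
    """Group peaks into isoform families by CH2 / water mass relations.

    An edge joins two peaks whose m/z difference lies within tolerance of
    14.0156500 Da (CH2) or 18.0105646 Da (water); connected components of the
    resulting graph become families. Peaks with no partner are returned as
    singleton families — contaminants are first-class output, not errors.
    Families are sorted by size (largest first) then lightest member, and the
    whole procedure is invariant under permutation of the input.
    """
    if ch2_tol <= 0 or water_tol <= 0:
        raise ValueError("tolerances must be positive")
    peaks = sorted(peaks, key=lambda p: (p.mz, p.rt, p.id))
    if not peaks:
        raise ValueError("peak list is empty")
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peak ids in input")
    by_id = {p.id: p for p in peaks}

    edges = _resolve_conflicts(_candidate_edges(peaks, ch2_tol, water_tol), by_id)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from((e.from_peak, e.to_peak) for e in edges)

    families = []
    for component in nx.connected_components(graph):
        members = sorted((by_id[i] for i in component), key=lambda p: p.mz)
        family_edges = sorted(
            (e for e in edges if e.from_peak in component),
            key=lambda e: (by_id[e.from_peak].mz, e.kind),
        )
        families.append(
            IsoformFamily(
                members=[IsoformAssignment(peak=p) for p in members],
                edges=family_edges,
            )
        )
    families.sort(key=lambda f: (-len(f.members), f.members[0].peak.mz))
    return families


def classify_topology_ms1(family: IsoformFamily) -> IsoformFamily:
    """Call cyclic/linear from water edges; RT order violations warn only.

    For every water edge the heavier peak is the hydrolysed (linear) form and
    the lighter its cyclic partner. Linear forms are expected to elute
    earlier than their cyclic partners on reverse phase (the free carboxyl
    and hydroxyl make them more polar); when they do not, a warning is
    recorded. Peaks without a water edge but connected by CH2 rungs default
    to cyclic (the majority class of a homolog chain); isolated peaks stay
    unknown.
    """
    for member in family.members:
        member.topology = "cyclic" if family.edges else "unknown"

    for edge in family.edges:
        if edge.kind != "WATER":
            continue
        cyclic = family.member(edge.from_peak)
        linear = family.member(edge.to_peak)
        cyclic.topology = "cyclic"
        linear.topology = "linear"
        linear.evidence.append(
            f"water partner of {edge.from_peak} (Δ={edge.observed_delta:.4f} Da)"
        )
        cyclic.evidence.append(
            f"cyclic partner of {edge.to_peak} (Δ={edge.observed_delta:.4f} Da)"
        )
        if linear.peak.rt >= cyclic.peak.rt:
            family.warnings.append(
                f"linear candidate {linear.peak.id} (rt {linear.peak.rt:.2f}) does not "
                f"elute earlier than cyclic partner {cyclic.peak.id} "
                f"(rt {cyclic.peak.rt:.2f})"
            )
    for edge in family.edges:
        if edge.kind == "CH2":
            for member in (family.member(edge.from_peak), family.member(edge.to_peak)):
                member.evidence.append(
                    f"CH2 rung {edge.from_peak}->{edge.to_peak} "
                    f"(Δ={edge.observed_delta:.4f} Da)"
                )
    return family


def infer_tail_lengths(family: IsoformFamily, anchor: tuple[str, int]) -> IsoformFamily:
    """Propagate fatty-acid tail carbon counts from one anchored member.

    A CH2 edge changes the count by +1 toward the heavier member; a water
    edge leaves it unchanged (hydration state does not alter the tail).
    Propagation is breadth-first from the anchor; if two paths disagree the
    graph is chemically inconsistent and an error names the offending peak.
    Nominal integer offsets from the lightest cyclic member are recorded to
    mirror the 0/14/28/42 Da presentation of a family table.
    """
    anchor_id, anchor_carbons = anchor
    if anchor_id not in family:
        raise KeyError(f"anchor peak {anchor_id!r} is not in the family")
    family.anchor = (anchor_id, anchor_carbons)

    adjacency: dict[str, list[tuple[str, int]]] = {m.peak.id: [] for m in family.members}
    for edge in family.edges:
        step = 1 if edge.kind == "CH2" else 0
        adjacency[edge.from_peak].append((edge.to_peak, +step))
        adjacency[edge.to_peak].append((edge.from_peak, -step))

    carbons: dict[str, int] = {anchor_id: anchor_carbons}
    frontier = [anchor_id]
    while frontier:
        current = frontier.pop(0)
        for neighbour, step in adjacency[current]:
            proposed = carbons[current] + step
            if neighbour in carbons:
                if carbons[neighbour] != proposed:
                    raise ValueError(
                        f"inconsistent tail-carbon propagation at peak {neighbour!r}: "
                        f"{carbons[neighbour]} vs {proposed} via {current!r}"
                    )
            else:
                carbons[neighbour] = proposed
                frontier.append(neighbour)

    for member in family.members:
        member.tail_carbons = carbons.get(member.peak.id)
        if member.tail_carbons is None:
            family.warnings.append(
                f"peak {member.peak.id} is not connected to the anchor; tail length unassigned"
            )

    cyclic_mzs = [m.peak.mz for m in family.members if m.topology == "cyclic"]
    if cyclic_mzs:
        lightest = min(cyclic_mzs)
        for member in family.members:
            member.nominal_offset = round(member.peak.mz - lightest)
    else:
        family.warnings.append("no cyclic member; nominal offsets unassigned")
    return family


def _letters() -> Iterable[str]:
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def assign_designations(family: IsoformFamily) -> IsoformFamily:
    """Letter the cyclic members by ascending mass; linear members follow partners.

    Cyclic members get A, B, C, ... in increasing m/z. A linear member takes
    the letter of the cyclic partner on its water edge plus an ``_L``
    subscript; a linear member without a partner falls back to the letter of
    the cyclic member sharing its tail carbon count (with a warning).
    """
    cyclic = sorted(
        (m for m in family.members if m.topology == "cyclic"), key=lambda m: m.peak.mz
    )
    for member, letter in zip(cyclic, _letters()):
        member.designation = letter

    partner_of = {
        e.to_peak: e.from_peak for e in family.edges if e.kind == "WATER"
    }
    by_carbons = {m.tail_carbons: m.designation for m in cyclic if m.tail_carbons is not None}
    for member in family.members:
        if member.topology != "linear":
            continue
        partner_id = partner_of.get(member.peak.id)
        if partner_id is not None:
            member.designation = f"{family.member(partner_id).designation}_L"
        elif member.tail_carbons in by_carbons:
            member.designation = f"{by_carbons[member.tail_carbons]}_L"
            family.warnings.append(
                f"linear peak {member.peak.id} has no water partner; designation "
                f"inferred from tail carbon count"
            )
        else:
            member.designation = "?_L"
            family.warnings.append(
                f"linear peak {member.peak.id} has neither water partner nor tail "
                f"count; designation undetermined"
            )
    for member in family.members:
        if member.designation is None:  # unknown topology, e.g. singleton
            member.designation = "?"
    return family


def annotate_peaks(
    peaks: Iterable[ObservedPeak],
    anchor: tuple[str, int] | None = None,
    ch2_tol: float = DEFAULT_CH2_TOL,
    water_tol: float = DEFAULT_WATER_TOL,
) -> list[IsoformFamily]:
    """Full MS1 pipeline: detect, classify, (optionally) anchor, designate."""
    families = detect_ladders(peaks, ch2_tol=ch2_tol, water_tol=water_tol)
    for family in families:
        classify_topology_ms1(family)
        if anchor is not None and anchor[0] in family:
            infer_tail_lengths(family, anchor)
        assign_designations(family)
    return families
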