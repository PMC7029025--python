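"""Theoretical masses for cyclic and linear lipopeptide hypotheses.

A lipopeptide here is a peptide whose N-terminal residue is acylated by a
beta-hydroxy fatty acid. The saturated free acid with n carbons has formula
CnH2nO3 (e.g. C12H24O3 for the 12-carbon tail). Two topologies exist:

* ``linear`` — the tail's beta-hydroxyl and the peptide's C-terminal carboxyl
  are both free; the neutral mass is the residue-mass sum plus the free-acid
  tail mass (the amide bond's water loss cancels the water the free termini
  would add).
* ``cyclic`` — a lactone (depsipeptide ester) closes the ring between the
  beta-hydroxyl and the C-terminal carboxyl, losing one further water, so the
  cyclic form is exactly one water (18.0105646 Da) lighter than its linear
  counterpart.

Vendor sequencing software instead folds waters into printed "lipid tail
formulas" such as C12H22O4; those labels are accepted via
:func:`tail_label_to_spec` and converted to this free-acid convention, which
is the one auditable bookkeeping used everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .chem import (
    CONSTANTS,
    DEFAULT_RESIDUE_TABLE,
    ElementalFormula,
    ResidueMassTable,
    mono_mass,
    residue_sum,
)

__all__ = [
    "TOPOLOGIES",
    "LipopeptideSpec",
    "CompositionFit",
    "tail_formula",
    "tail_label_to_spec",
    "assemble_neutral",
    "protonated_mz",
    "composition_fit",
]

TOPOLOGIES = ("cyclic", "linear")


@dataclass(frozen=True, order=True)
class LipopeptideSpec:
    """A composition hypothesis: peptide sequence + tail length + topology.

    ``tail_saturated=False`` models one C=C double bond in the tail (two
    hydrogens fewer); chain branching is mass-silent and not represented.
    """

    sequence: str
    tail_carbons: int
    topology: str = "cyclic"
    tail_saturated: bool = True

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if self.tail_carbons < 3:
            raise ValueError(f"tail_carbons must be >= 3, got {self.tail_carbons}")
        if len(self.sequence) < 1:
            raise ValueError("sequence must contain at least one residue")


def tail_formula(tail_carbons: int, saturated: bool = True) -> ElementalFormula:
    """Formula of the free beta-hydroxy fatty acid: CnH2nO3 (minus H2 if unsaturated)."""
    if tail_carbons < 3:
        raise ValueError(f"tail_carbons must be >= 3, got {tail_carbons}")
    hydrogens = 2 * tail_carbons - (0 if saturated else 2)
    return ElementalFormula({"C": tail_carbons, "H": hydrogens, "O": 3})


def tail_label_to_spec(label: str, sequence: str = "LLLVDLL") -> LipopeptideSpec:
    """Map a vendor-style lipid-tail formula label (e.g. ``"C12H22O4"``) to a spec.

    The mapping ships as a plain-text table; unknown labels raise ``KeyError``.
    """
    text = resources.files("lipoladder.data").joinpath("tail_formula_labels.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#") or line.startswith("label") or not line.strip():
            continue
        lab, carbons, topology = line.split("\t")
        if lab == label:
            return LipopeptideSpec(sequence, int(carbons), topology)
    raise KeyError(f"unknown lipid-tail formula label {label!r}")


def assemble_neutral(spec: LipopeptideSpec, table: ResidueMassTable | None = None) -> float:
    """Neutral monoisotopic mass in Da of a lipopeptide hypothesis.

    linear:  M = sum(residue masses) + mass(CnH2nO3)
    cyclic:  M = linear - water        (lactone closure)

    so ``assemble(linear) - assemble(cyclic) == CONSTANTS.water`` for any spec.
    """
    table = table or DEFAULT_RESIDUE_TABLE
    mass = residue_sum(spec.sequence, table) + mono_mass(
        tail_formula(spec.tail_carbons, spec.tail_saturated)
    )
    if spec.topology == "cyclic":
        mass -= CONSTANTS.water
    return mass


def protonated_mz(neutral: float) -> float:
    """m/z of the singly protonated ion [M+H]+ (positive electrospray)."""
    if neutral < 0:
        raise ValueError(f"neutral mass must be non-negative, got {neutral}")
    return neutral + CONSTANTS.proton


@dataclass(frozen=True)
class CompositionFit:
    """How well one composition hypothesis explains an observed m/z."""

    spec: LipopeptideSpec
    theoretical_mz: float
    delta: float  # observed - theoretical, Da
    ppm: float

    @property
    def within(self) -> bool:
        """True when |ppm| is inside the default 30 ppm reporting window."""
        return abs(self.ppm) <= DEFAULT_PPM_WINDOW


#: Reporting window for calling a composition a "match". Wide enough that the
#: best chemically sensible composition for real Q-TOF family data (which can
#: sit ~27 ppm from a printed mean) is admitted; tighten per instrument.
DEFAULT_PPM_WINDOW = 30.0


def composition_fit(
    observed_mz: float,
    candidates: Iterable[LipopeptideSpec],
    table: ResidueMassTable | None = None,
) -> Sequence[CompositionFit]:
    """Rank candidate compositions against an observed protonated m/z.

    Returns one fit per candidate sorted by |ppm| ascending, with a
    deterministic tie-break on (tail_carbons, topology, sequence) so the
    ordering is invariant under permutation of the candidate collection.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    table = table or DEFAULT_RESIDUE_TABLE
    fits = []
    for spec in candidates:
        theoretical = protonated_mz(assemble_neutral(spec, table))
        delta = observed_mz - theoretical
        fits.append(
            CompositionFit(spec, theoretical, delta, delta / theoretical * 1e6)
        )
    fits.sort(key=lambda f: (abs(f.ppm), f.spec.tail_carbons, f.spec.topology, f.spec.sequence))
    return fits
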