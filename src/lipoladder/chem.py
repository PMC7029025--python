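"""Exact elemental-formula and monoisotopic-mass arithmetic.

Every mass in the package flows through this module: formulas are integer
element-count vectors over {C, H, N, O, S}, masses are monoisotopic sums over
a pinned atomic-mass table, and the amino-acid residue table ships as a
versioned TSV so tests can pin exact values.

Only monoisotopic masses are supported: the peaks this package annotates are
Q-TOF centroids of singly protonated species, for which average masses are
never the right bookkeeping.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ALLOWED_ELEMENTS",
    "ATOMIC_MASSES",
    "ElementalFormula",
    "MassConstants",
    "ResidueMassTable",
    "CONSTANTS",
    "DEFAULT_RESIDUE_TABLE",
    "parse_formula",
    "format_formula",
    "mono_mass",
    "residue_sum",
]

ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_atomic_masses() -> Mapping[str, float]:
    masses: dict[str, float] = {}
    text = resources.files("lipoladder.data").joinpath("atomic_masses.tsv").read_text()
    for row in csv.DictReader(
        (line for line in text.splitlines() if not line.startswith("#")), delimiter="\t"
    ):
        masses[row["symbol"]] = float(row["mass"])
    return MappingProxyType(masses)


#: Pinned monoisotopic atomic masses in Da (C is exactly 12 by definition).
ATOMIC_MASSES: Mapping[str, float] = _load_atomic_masses()

#: Mass of a proton in Da; [M+H]+ = M + PROTON_MASS for singly charged ions.
PROTON_MASS = 1.00727646

#: Electron rest mass in Da (kept for completeness of the constant set).
ELECTRON_MASS = 0.00054857990924


@dataclass(frozen=True)
class ElementalFormula:
    """An immutable vector of element counts, e.g. ``C12H24O3``.

    Supports element-wise ``+`` and ``-`` (subtraction going negative is an
    error: a molecule cannot contain a negative number of atoms) and integer
    scaling with ``*``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in ALLOWED_ELEMENTS:
                raise ValueError(
                    f"unknown element {element!r}; supported: {', '.join(ALLOWED_ELEMENTS)}"
                )
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"count for {element} must be a non-negative integer, got {count!r}")
            if count:
                clean[element] = count
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            remaining = merged.get(element, 0) - count
            if remaining < 0:
                raise ValueError(
                    f"subtraction would give {remaining} atoms of {element}"
                )
            merged[element] = remaining
        return ElementalFormula(merged)

    def __mul__(self, n: int) -> "ElementalFormula":
        if not isinstance(n, int) or n < 0:
            raise ValueError("formula scaling requires a non-negative integer")
        return ElementalFormula({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __str__(self) -> str:
        return format_formula(self)

    @property
    def mass(self) -> float:
        return mono_mass(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C12H22O4"``.

    Each element symbol may be followed by an optional positive count;
    repeated symbols accumulate. Raises ``ValueError`` on empty input,
    unknown symbols or malformed counts.
    """
    if not text:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    position = 0
    for match in _FORMULA_RE.finditer(text):
        if match.start() != position:
            raise ValueError(f"malformed formula {text!r} at position {position}")
        position = match.end()
        element, digits = match.groups()
        if element not in ALLOWED_ELEMENTS:
            raise ValueError(f"unknown element {element!r} in formula {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise ValueError(f"zero count for {element} in formula {text!r}")
        counts[element] = counts.get(element, 0) + count
    if position != len(text):
        raise ValueError(f"malformed formula {text!r} at position {position}")
    return ElementalFormula(counts)


def format_formula(formula: ElementalFormula) -> str:
    """Render in Hill order for CHNOS organics: C, H, then N, O, S."""
    parts = []
    for element in ALLOWED_ELEMENTS:  # tuple is already in Hill order
        count = formula[element]
        if count:
            parts.append(element if count == 1 else f"{element}{count}")
    return "".join(parts)


def mono_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da: sum of count x atomic mass; additive by construction."""
    return sum(ATOMIC_MASSES[el] * count for el, count in formula.counts.items())


@dataclass(frozen=True)
class MassConstants:
    """The canonical mass deltas of the annotation logic, in Da."""

    proton: float
    water: float
    methylene: float
    electron: float


#: water = H2O (the cyclic/linear 18 Da split); methylene = CH2 (the homolog
#: ladder 14 Da rung). Derived from the atomic table, not typed in.
CONSTANTS = MassConstants(
    proton=PROTON_MASS,
    water=mono_mass(parse_formula("H2O")),
    methylene=mono_mass(parse_formula("CH2")),
    electron=ELECTRON_MASS,
)


class ResidueMassTable:
    """Amino-acid residue formulas and monoisotopic masses.

    The default table covers the 19 one-letter codes with distinct residue
    masses plus I (isobaric with L); every stored mass is validated against
    the mass computed from its own formula to 1e-6 Da at load time.
    """

    def __init__(self, entries: Mapping[str, tuple[ElementalFormula, float]]):
        for letter, (formula, mass) in entries.items():
            if abs(mono_mass(formula) - mass) > 1e-6:
                raise ValueError(
                    f"residue {letter}: stored mass {mass} disagrees with formula "
                    f"{format_formula(formula)} ({mono_mass(formula):.7f})"
                )
        self._entries = dict(entries)

    def __contains__(self, letter: str) -> bool:
        return letter in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def formula(self, letter: str) -> ElementalFormula:
        return self._lookup(letter)[0]

    def mass(self, letter: str) -> float:
        return self._lookup(letter)[1]

    def _lookup(self, letter: str) -> tuple[ElementalFormula, float]:
        try:
            return self._entries[letter]
        except KeyError:
            raise KeyError(f"unknown residue letter {letter!r}") from None

    @classmethod
    def from_tsv(cls, text: str) -> "ResidueMassTable":
        entries = {}
        rows = csv.DictReader(
            (line for line in text.splitlines() if not line.startswith("#")),
            delimiter="\t",
        )
        for row in rows:
            entries[row["symbol"]] = (parse_formula(row["formula"]), float(row["mass"]))
        return cls(entries)

    @classmethod
    def default(cls) -> "ResidueMassTable":
        text = resources.files("lipoladder.data").joinpath("residue_masses.tsv").read_text()
        return cls.from_tsv(text)


DEFAULT_RESIDUE_TABLE = ResidueMassTable.default()


def residue_sum(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Sum of residue masses for a one-letter sequence (no termini, no water).

    The empty sequence sums to 0.0; an unknown letter raises ``KeyError``.
    """
    table = table or DEFAULT_RESIDUE_TABLE
    return sum(table.mass(letter) for letter in sequence)
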