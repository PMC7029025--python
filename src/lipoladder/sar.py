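"""Tail-length structure-activity analysis for a lipopeptide isoform family.

The biological readout is antimicrobial potency — inhibition-zone size and
minimum inhibitory concentration (MIC) — of each cyclic isoform against a
bacterial and a fungal test strain. The question is ordinal: does potency
rise or fall with fatty-acid tail length? Accordingly the trend statistic is
Spearman's rank correlation of tail carbons against the response mean (four
isoforms support no linearity claim), and a per-isoform selectivity index
MIC(fungi)/MIC(bacteria) locates where preference crosses from bacteria
(ratio > 1) to fungi (ratio < 1). A parametric bootstrap that resamples each
mean from a normal with its reported SD quantifies how stable the trend sign
is given only summary statistics of triplicate assays.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ActivityRecord",
    "TrendResult",
    "SelectivityReport",
    "load_activity_table",
    "trend",
    "selectivity_index",
    "bootstrap_trend",
]

ORGANISM_CLASSES = ("bacteria", "fungi")
RESPONSES = ("mic", "zone")


@dataclass(frozen=True)
class ActivityRecord:
    """One isoform x organism-class activity row (means ± SD of triplicates)."""

    designation: str
    tail_carbons: int
    organism_class: str
    zone_mean: float  # mm
    zone_sd: float
    mic_mean: float  # µg/ml
    mic_sd: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.organism_class not in ORGANISM_CLASSES:
            raise ValueError(f"organism_class must be one of {ORGANISM_CLASSES}")
        if self.mic_mean <= 0:
            raise ValueError("MIC mean must be positive")
        if self.mic_sd < 0 or self.zone_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def response(self, which: str) -> tuple[float, float]:
        if which == "mic":
            return self.mic_mean, self.mic_sd
        if which == "zone":
            return self.zone_mean, self.zone_sd
        raise ValueError(f"response must be one of {RESPONSES}")


def load_activity_table() -> list[ActivityRecord]:
    """The bundled four-isoform (C12–C15) activity fixture."""
    text = resources.files("lipoladder.data").joinpath("activity.csv").read_text()
    rows = csv.DictReader(line for line in text.splitlines() if not line.startswith("#"))
    return [
        ActivityRecord(
            designation=row["designation"],
            tail_carbons=int(row["tail_carbons"]),
            organism_class=row["organism_class"],
            zone_mean=float(row["zone_mm_mean"]),
            zone_sd=float(row["zone_mm_sd"]),
            mic_mean=float(row["mic_mean"]),
            mic_sd=float(row["mic_sd"]),
            note=row.get("zone_note", ""),
        )
        for row in rows
    ]


@dataclass(frozen=True)
class TrendResult:
    rho: float
    direction: str  # increasing | decreasing | flat


def _class_records(
    records: Iterable[ActivityRecord], organism_class: str
) -> list[ActivityRecord]:
    selected = sorted(
        (r for r in records if r.organism_class == organism_class),
        key=lambda r: r.tail_carbons,
    )
    if len({r.tail_carbons for r in selected}) < 3:
        raise ValueError(
            f"need >= 3 records with distinct tail lengths for {organism_class!r}, "
            f"got {len(selected)}"
        )
    return selected


def trend(
    records: Iterable[ActivityRecord], organism_class: str, response: str = "mic"
) -> TrendResult:
    """Spearman rank correlation of tail carbons vs the response mean.

    Direction is the sign of rho, with |rho| < 0.5 reported as flat. A
    constant response vector leaves the correlation undefined and raises.
    """
    selected = _class_records(records, organism_class)
    carbons = [r.tail_carbons for r in selected]
    values = [r.response(response)[0] for r in selected]
    if len(set(values)) == 1:
        raise ValueError(f"constant {response} response; rank correlation undefined")
    rho = float(stats.spearmanr(carbons, values).statistic)
    if abs(rho) < 0.5:
        direction = "flat"
    else:
        direction = "increasing" if rho > 0 else "decreasing"
    return TrendResult(rho=rho, direction=direction)


@dataclass(frozen=True)
class SelectivityReport:
    """MIC(fungi)/MIC(bacteria) per isoform; > 1 means bacteria-selective."""

    ratios: dict[str, float]  # designation -> ratio, ascending tail carbons
    crossover: tuple[str, str] | None  # adjacent pair bracketing ratio 1


def selectivity_index(records: Iterable[ActivityRecord]) -> SelectivityReport:
    """Per-isoform fungal/bacterial MIC ratio and the tail-length crossover.

    Requires both organism classes for every isoform. The crossover is the
    adjacent (by tail length) isoform pair whose ratios bracket 1 — the point
    where the family's preference flips from bacteria to fungi.
    """
    by_iso: dict[str, dict[str, ActivityRecord]] = {}
    for record in records:
        by_iso.setdefault(record.designation, {})[record.organism_class] = record
    ratios: dict[str, float] = {}
    ordered = sorted(
        by_iso.items(),
        key=lambda kv: next(iter(kv[1].values())).tail_carbons,
    )
    for designation, classes in ordered:
        missing = [c for c in ORGANISM_CLASSES if c not in classes]
        if missing:
            raise ValueError(f"isoform {designation}: missing class {missing[0]!r}")
        ratios[designation] = classes["fungi"].mic_mean / classes["bacteria"].mic_mean
    crossover = None
    names = list(ratios)
    for left, right in zip(names, names[1:]):
        if (ratios[left] - 1) * (ratios[right] - 1) < 0:
            crossover = (left, right)
            break
    return SelectivityReport(ratios=ratios, crossover=crossover)


def bootstrap_trend(
    records: Iterable[ActivityRecord],
    organism_class: str,
    response: str = "mic",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of parametric-bootstrap resamples preserving the trend's sign.

    Each response mean is resampled from N(mean, sd) — all the source assays
    report — and Spearman's rho recomputed; ties in a resample count as not
    preserving the sign. Deterministic given the seed; requires
    ``n_boot >= 100`` for a stable fraction.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = trend(records, organism_class, response)
    sign = np.sign(point.rho)
    selected = _class_records(records, organism_class)
    means = np.array([r.response(response)[0] for r in selected])
    sds = np.array([r.response(response)[1] for r in selected])
    carbons = np.array([r.tail_carbons for r in selected])
    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_boot, len(means)))
    preserved = 0
    for row in draws:
        rho = stats.spearmanr(carbons, row).statistic
        if np.sign(rho) == sign:
            preserved += 1
    return preserved / n_boot
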