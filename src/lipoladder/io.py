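"""Readers, writers and run configuration.

File dialects are deliberately minimal and text-based: peak lists are CSV
with header ``rt_min,mz,intensity[,id]`` (retention time always in minutes,
m/z always the singly protonated value), MS2 spectra are MGF, reports are
JSON (full evidence trail) plus a flat CSV mirroring the family-table
presentation, and run configuration is a flat ``key = value`` file with
unknown keys rejected loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .ladder import (
    DEFAULT_CH2_TOL,
    DEFAULT_WATER_TOL,
    IsoformFamily,
    ObservedPeak,
)
from .fragments import DEFAULT_DAUGHTER_TOL, DEFAULT_FRAG_TOL, SpectrumMatch
from .model import DEFAULT_PPM_WINDOW

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "read_peaklist",
    "write_peaklist",
    "bundled_peaklist",
    "read_ms2",
    "write_ms2",
    "write_report",
    "write_truth",
]

logger = logging.getLogger("lipoladder")

_PEAK_COLUMNS = ("rt_min", "mz", "intensity")


@dataclass
class RunConfig:
    """Flat configuration for an annotation run; all tolerances in Da."""

    ch2_tol: float = DEFAULT_CH2_TOL
    water_tol: float = DEFAULT_WATER_TOL
    frag_tol: float = DEFAULT_FRAG_TOL
    daughter_tol: float = DEFAULT_DAUGHTER_TOL
    ppm_window: float = DEFAULT_PPM_WINDOW
    anchor_id: str = ""
    anchor_carbons: int = 0
    sequences: str = "LLLVDLL"  # comma-separated candidate sequences
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("ch2_tol", "water_tol", "frag_tol", "daughter_tol", "ppm_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def anchor(self) -> tuple[str, int] | None:
        if self.anchor_id and self.anchor_carbons:
            return (self.anchor_id, self.anchor_carbons)
        return None


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        ftype = fields[key].type
        if ftype in ("float", float):
            values[key] = float(value)
        elif ftype in ("int", int):
            values[key] = int(value)
        else:
            values[key] = value
    return RunConfig(**values)


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [
        f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(RunConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaklist(path: str | Path) -> list[ObservedPeak]:
    """Read a peak-list CSV (``rt_min,mz,intensity[,id]``; ``#`` comments).

    Missing ids are auto-generated from the row index; a missing column or a
    non-numeric cell raises with the offending column (and row) named.
    """
    frame = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in _PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column {missing[0]!r}")
    peaks = []
    for row_idx, row in frame.iterrows():
        numeric = {}
        for column in _PEAK_COLUMNS:
            try:
                numeric[column] = float(row[column])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {row[column]!r} in column "
                    f"{column!r}, row {row_idx}"
                ) from None
        peak_id = str(row["id"]) if "id" in frame.columns else str(row_idx)
        peaks.append(
            ObservedPeak(peak_id, numeric["rt_min"], numeric["mz"], numeric["intensity"])
        )
    return peaks


def write_peaklist(peaks: Iterable[ObservedPeak], path: str | Path) -> None:
    frame = pd.DataFrame(
        [{"rt_min": p.rt, "mz": p.mz, "intensity": p.intensity, "id": p.id} for p in peaks]
    )
    frame.to_csv(path, index=False)


def bundled_peaklist() -> list[ObservedPeak]:
    """The packaged six-peak isoform-family fixture."""
    from importlib import resources

    with resources.as_file(
        resources.files("lipoladder.data").joinpath("tic_peaks.csv")
    ) as path:
        return read_peaklist(path)


def read_ms2(path: str | Path) -> list[tuple[float, list[tuple[float, float]]]]:
    """Read an MGF file into (precursor m/z, [(mz, intensity), ...]) pairs.

    Blocks without a PEPMASS are skipped with a logged warning rather than
    aborting the run.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.warning(
                    "skipping MGF block %r without PEPMASS", params.get("title", "?")
                )
                continue
            peaks = list(
                zip((float(x) for x in block["m/z array"]),
                    (float(y) for y in block["intensity array"]))
            )
            spectra.append((float(pepmass[0]), peaks))
    return spectra


def write_ms2(
    spectra: Iterable[tuple[float, Sequence[tuple[float, float]]]], path: str | Path
) -> None:
    """Write (precursor, peaks) pairs as MGF (round-trips through read_ms2)."""
    entries = []
    for index, (precursor, peaks) in enumerate(spectra):
        entries.append(
            {
                "m/z array": [mz for mz, _ in peaks],
                "intensity array": [i for _, i in peaks],
                "params": {"title": f"spectrum_{index}", "pepmass": precursor},
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def _family_dict(family: IsoformFamily) -> dict:
    return {
        "anchor": list(family.anchor) if family.anchor else None,
        "warnings": list(family.warnings),
        "edges": [dataclasses.asdict(e) for e in family.edges],
        "members": [
            {
                "id": m.peak.id,
                "designation": m.designation,
                "rt_min": m.peak.rt,
                "mz": m.peak.mz,
                "intensity": m.peak.intensity,
                "topology": m.topology,
                "tail_carbons": m.tail_carbons,
                "nominal_offset": m.nominal_offset,
                "evidence": list(m.evidence),
            }
            for m in family.members
        ],
    }


def write_report(
    families: Sequence[IsoformFamily],
    json_path: str | Path,
    csv_path: str | Path | None = None,
    matches: Sequence[SpectrumMatch] = (),
) -> None:
    """Write the annotation report: JSON with full evidence, CSV summary.

    The CSV mirrors the columns of a printed family table: designation,
    retention time, protonated mass, topology, tail length, and the nominal
    mass offset from the lightest cyclic member. Output is deterministic:
    rerunning on the same input is byte-identical.
    """
    payload = {
        "families": [_family_dict(f) for f in families],
        "ms2_matches": [
            {
                "parent_mz": m.parent_mz,
                "coverage": m.coverage,
                "topology_call": m.topology_call,
                "matched": [
                    {"series": ion.series, "index": ion.index,
                     "theoretical_mz": ion.mz, "observed_mz": obs, "delta": delta}
                    for ion, obs, delta in m.matched
                ],
            }
            for m in matches
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        rows = []
        for family_idx, family in enumerate(families):
            for m in family.members:
                rows.append(
                    {
                        "family": family_idx,
                        "designation": m.designation,
                        "rt_min": m.peak.rt,
                        "mz": m.peak.mz,
                        "topology": m.topology,
                        "tail_carbons": m.tail_carbons,
                        "mass_offset_da": m.nominal_offset,
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def write_truth(truth: Sequence, path: str | Path) -> None:
    """Write a simulation truth table as CSV."""
    rows = []
    for row in truth:
        rows.append(
            {
                "peak_id": row.peak_id,
                "designation": row.designation,
                "topology": row.topology,
                "tail_carbons": row.tail_carbons,
                "true_mz": row.true_mz,
                "true_rt": row.true_rt,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
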