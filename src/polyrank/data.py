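"""Polymer records and degradability-dataset I/O.

A polymer is a repeat unit written as SMILES in which ``*`` (wildcard) atoms
mark the polymerization points; they are legal graph atoms and are never
stripped.  A :class:`DegradationDataset` holds polymers together with a scalar
degradability value measured under one experimental condition; values are
comparable only *within* a dataset, which is exactly why the ranking model
downstream trains on within-dataset preference pairs rather than on the raw
values.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    SmilesParseError,
    ValidationError,
)

RDLogger.DisableLog("rdApp.*")

#: Unicode glyphs that publishers substitute for the ASCII wildcard star.
_STAR_GLYPHS = "∗✱﹡＊"

_WS = re.compile(r"\s+")


def normalize_smiles_text(text: str) -> str:
    """Map typographic star glyphs to ASCII ``*`` and drop stray whitespace.

    SMILES contains no whitespace, so spaces inserted by text extraction
    (e.g. ``"(∗) = O"``) can be removed without ambiguity.
    """
    for glyph in _STAR_GLYPHS:
        text = text.replace(glyph, "*")
    return _WS.sub("", text)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a repeat-unit SMILES (wildcard ``*`` allowed) or raise."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(normalize_smiles_text(smiles))
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of ``smiles``.

    Idempotent; two spellings of the same molecular graph map to the same
    string, and attachment-point ``*`` atoms are preserved.
    """
    return Chem.MolToSmiles(parse_smiles(smiles))


@dataclass(frozen=True)
class Polymer:
    """A repeat unit with provenance.

    ``smiles`` is stored canonicalized; the spelling found in the source
    table is kept in ``source_smiles``.
    """

    id: str
    name: str
    abbreviation: str
    smiles: str
    dataset_id: str = ""
    source_smiles: str = ""

    def mol(self) -> Chem.Mol:
        return parse_smiles(self.smiles)


@dataclass(frozen=True)
class RejectedRow:
    index: int
    smiles: str
    reason: str


@dataclass
class ParseReport:
    """Book-keeping for a table read: nothing is dropped silently."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[RejectedRow] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class DegradationDataset:
    """Polymers plus degradability values measured under one condition."""

    id: str
    records: list[tuple[Polymer, float]]
    units: str = ""
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyDatasetError(f"dataset {self.id!r} has no records")
        seen: dict[str, str] = {}
        abbrs: set[str] = set()
        for polymer, value in self.records:
            if not (value >= 0.0 and value == value and value != float("inf")):
                raise ValidationError(
                    f"dataset {self.id!r}: value {value!r} for "
                    f"{polymer.abbreviation} must be finite and >= 0"
                )
            if polymer.smiles in seen:
                raise ValidationError(
                    f"dataset {self.id!r}: duplicate SMILES for "
                    f"{polymer.abbreviation} and {seen[polymer.smiles]} — "
                    "a within-dataset duplicate makes the preference ill-defined"
                )
            seen[polymer.smiles] = polymer.abbreviation
            if polymer.abbreviation in abbrs:
                raise ValidationError(
                    f"dataset {self.id!r}: duplicate abbreviation "
                    f"{polymer.abbreviation!r}"
                )
            abbrs.add(polymer.abbreviation)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def polymers(self) -> list[Polymer]:
        return [p for p, _ in self.records]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": [self.id] * len(self),
                "abbreviation": [p.abbreviation for p in self.polymers],
                "name": [p.name for p in self.polymers],
                "smiles": [p.smiles for p in self.polymers],
                "value": self.values,
                "units": [self.units] * len(self),
            }
        )


_DEFAULT_COLUMN_MAP = {"smiles": "smiles", "value": "value"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    sep = "\t" if suffix in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str = "dataset",
    units: str = "",
) -> DegradationDataset:
    """Read a CSV/TSV/XLSX degradability table into a dataset.

    ``column_map`` maps the roles {smiles, value, name?, abbreviation?} to
    column names; it defaults to ``{"smiles": "smiles", "value": "value"}``.
    Rows whose SMILES does not parse or whose value is not a non-negative
    real are rejected and listed in ``dataset.report``.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = _read_table(path)
    for role in ("smiles", "value"):
        if cmap[role] not in frame.columns:
            raise ConfigurationError(
                f"column {cmap[role]!r} (role {role!r}) not in {list(frame.columns)}"
            )
    return dataset_from_frame(frame, cmap, dataset_id=dataset_id, units=units)


def dataset_from_frame(
    frame: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str = "dataset",
    units: str = "",
) -> DegradationDataset:
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    report = ParseReport(n_rows=len(frame))
    records: list[tuple[Polymer, float]] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        raw_smiles = str(row_d[cmap["smiles"]])
        try:
            canon = canonicalize(raw_smiles)
        except SmilesParseError as exc:
            report.rejected.append(RejectedRow(i, raw_smiles, str(exc)))
            continue
        try:
            value = float(row_d[cmap["value"]])
        except (TypeError, ValueError):
            report.rejected.append(
                RejectedRow(i, raw_smiles, f"value {row_d[cmap['value']]!r} is not a number")
            )
            continue
        if not (value >= 0.0):
            report.rejected.append(
                RejectedRow(i, raw_smiles, f"value {value!r} is negative or NaN")
            )
            continue
        name = str(row_d.get(cmap.get("name", ""), "")) if cmap.get("name") else ""
        abbr = (
            str(row_d.get(cmap.get("abbreviation", ""), ""))
            if cmap.get("abbreviation")
            else ""
        )
        if not abbr:
            abbr = name or f"P{i:03d}"
        records.append(
            (
                Polymer(
                    id=f"{dataset_id}:{abbr}",
                    name=name or abbr,
                    abbreviation=abbr,
                    smiles=canon,
                    dataset_id=dataset_id,
                    source_smiles=raw_smiles,
                ),
                value,
            )
        )
    report.n_accepted = len(records)
    if not records:
        raise EmptyDatasetError(
            f"dataset {dataset_id!r}: no valid rows ({report.n_rejected} rejected)"
        )
    return DegradationDataset(id=dataset_id, records=records, units=units, report=report)


def write_dataset(dataset: DegradationDataset, path: str | Path, header_comment: str = "") -> None:
    """Write the canonical TSV form (round-trips through :func:`read_dataset`)."""
    path = Path(path)
    frame = dataset.to_frame()
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_canonical_tsv(path: str | Path, dataset_id: str | None = None) -> DegradationDataset:
    """Read a TSV previously produced by :func:`write_dataset`."""
    frame = _read_table(path)
    did = dataset_id or (str(frame["dataset_id"].iloc[0]) if "dataset_id" in frame else "dataset")
    units = str(frame["units"].iloc[0]) if "units" in frame.columns else ""
    return dataset_from_frame(
        frame,
        {"smiles": "smiles", "value": "value", "name": "name", "abbreviation": "abbreviation"},
        dataset_id=did,
        units=units,
    )
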