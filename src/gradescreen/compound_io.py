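"""Compound record parsing, validation, canonicalization, and deduplication.

A screening library arrives as a SMILES file, a CSV table, or an SDF; before
any scoring every record is reduced to a canonical isomeric structure key and
the library is filtered to first-occurrence unique, structurally valid
entries.  Everything removed is accounted for in a :class:`RejectionLog` so
that ``|input| = |kept| + |rejected|`` always holds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Reason codes, in precedence order (first failing check wins).
REASON_MISSING = "missing-smiles"
REASON_UNPARSEABLE = "unparseable-smiles"
REASON_DUPLICATE = "duplicate-structure"


@dataclass(frozen=True)
class CompoundRecord:
    """One compound as read from an input table (no structure perception yet)."""

    identifier: str
    name: str
    smiles: str
    source: str = "input"


@dataclass
class RejectionLog:
    """Accounting of every record removed by :func:`filter_valid_unique`."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, identifier: str, reason: str) -> None:
        self.entries.append((identifier, reason))

    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.entries:
            out[reason] = out.get(reason, 0) + 1
        return out


class EmptyLibraryError(ValueError):
    """Raised when an input file contains no compound records at all."""


def parse_compound_table(path: str | Path, format: str) -> list[CompoundRecord]:
    """Read compound records from ``path``.

    ``format`` is one of ``smiles`` (one SMILES per line, optional
    whitespace-separated name), ``csv`` (header ``identifier,name,smiles``),
    or ``sdf`` (V2000; untitled molecule blocks get identifiers
    ``mol_<index>``).  Records are returned in file order with no structure
    perception beyond what SDF reading requires.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"compound table not found: {path}")
    if format == "smiles":
        records = list(_parse_smiles_lines(path))
    elif format == "csv":
        records = list(_parse_csv(path))
    elif format == "sdf":
        records = list(_parse_sdf(path))
    else:
        raise ValueError(f"unknown compound table format: {format!r}")
    if not records:
        raise EmptyLibraryError(f"no compound records in {path}")
    return records


def _parse_smiles_lines(path: Path) -> Iterable[CompoundRecord]:
    with open(path) as fh:
        idx = 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            idx += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            ident = name if name else f"mol_{idx}"
            yield CompoundRecord(ident, name, smiles, source=str(path.name))


def _parse_csv(path: Path) -> Iterable[CompoundRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"identifier", "name", "smiles"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"CSV {path} must have header columns identifier,name,smiles "
                f"(got {reader.fieldnames})"
            )
        for row in reader:
            yield CompoundRecord(
                (row["identifier"] or "").strip(),
                (row["name"] or "").strip(),
                (row["smiles"] or "").strip(),
                source=str(path.name),
            )


def _parse_sdf(path: Path) -> Iterable[CompoundRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            # unreadable block: keep the record so the filter can reject it
            yield CompoundRecord(f"mol_{i}", "", "", source=str(path.name))
            continue
        title = (mol.GetProp("_Name") if mol.HasProp("_Name") else "").strip()
        ident = title if title else f"mol_{i}"
        yield CompoundRecord(ident, title, Chem.MolToSmiles(mol), source=str(path.name))


def canonical_structure_key(record: CompoundRecord) -> Optional[str]:
    """Canonical isomeric SMILES of the record's structure, or None.

    Two SMILES spellings of the same molecule map to the same key; stereo is
    preserved, so an isomeric and a non-isomeric spelling of a stereocenter
    are distinct structures here.  ``None`` signals missing or unparseable
    input and is consumed by :func:`filter_valid_unique` rather than raised.
    """
    smiles = record.smiles.strip()
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def filter_valid_unique(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], RejectionLog]:
    """Keep the first occurrence of each valid structure, logging removals.

    Reason-code precedence per record: missing-smiles, then
    unparseable-smiles, then duplicate-structure.  Kept records preserve
    input order; ``len(kept) + len(log) == len(records)``.
    """
    kept: list[CompoundRecord] = []
    log = RejectionLog()
    seen: set[str] = set()
    for rec in records:
        if not rec.smiles.strip():
            log.add(rec.identifier, REASON_MISSING)
            continue
        key = canonical_structure_key(rec)
        if key is None:
            log.add(rec.identifier, REASON_UNPARSEABLE)
            continue
        if key in seen:
            log.add(rec.identifier, REASON_DUPLICATE)
            continue
        seen.add(key)
        kept.append(rec)
    return kept, log


def write_library_csv(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records as a CSV with the canonical identifier,name,smiles header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["identifier", "name", "smiles"])
        for rec in records:
            writer.writerow([rec.identifier, rec.name, rec.smiles])


def write_rejection_log_csv(log: RejectionLog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["identifier", "reason"])
        writer.writerows(log.entries)
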