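"""Physicochemical descriptors, QED, synthetic accessibility, and structural alerts.

All values come from RDKit: Wildman–Crippen logP/MR (atom-contribution), the
Bickerton QED desirability composite, the Ertl–Schuffenhauer fragment-based
synthetic-accessibility score (raw 1 = easy … 10 = hard), and the standard
PAINS (A/B/C) and BRENK SMARTS catalogs via RDKit's FilterCatalog.
Descriptors are deterministic functions of the canonical structure, so
explicit- versus implicit-hydrogen SMILES spellings give identical results.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .compound_io import CompoundRecord

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402

KNOWN_CATALOGS = ("PAINS", "BRENK")

_CATALOGS: dict[str, FilterCatalog] = {}


def _catalog(name: str) -> FilterCatalog:
    if name not in _CATALOGS:
        params = FilterCatalogParams()
        params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, name))
        _CATALOGS[name] = FilterCatalog(params)
    return _CATALOGS[name]


@dataclass(frozen=True)
class DescriptorSet:
    """Everything the seven-component scorer consumes for one compound."""

    mw: float  # Da
    logp: float  # Wildman–Crippen estimate
    hbd: int
    hba: int
    rotb: int
    tpsa: float  # Å²
    molar_refractivity: float
    atom_count: int  # all atoms including hydrogens
    heavy_atoms: int
    aromatic_rings: int
    qed_raw: float  # [0, 1]
    sa_raw: float  # [1, 10], 1 = easiest to synthesize
    alerts: tuple[tuple[str, str], ...] = field(default_factory=tuple)


class StructureError(ValueError):
    """Raised when a record's SMILES cannot be perceived as a molecule."""


def _mol_from_record(record: CompoundRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise StructureError(
            f"record {record.identifier!r}: unparseable SMILES {record.smiles!r}"
        )
    return mol


def detect_alerts(
    record: CompoundRecord, catalogs: set[str] | frozenset[str] = frozenset(KNOWN_CATALOGS)
) -> list[tuple[str, str]]:
    """Structural-alert hits as (catalog, alert-name) pairs.

    ``catalogs`` is a subset of {"PAINS", "BRENK"}; an empty set yields an
    empty list.  PAINS here is the union of the A, B, and C families.
    """
    unknown = set(catalogs) - set(KNOWN_CATALOGS)
    if unknown:
        raise ValueError(f"unknown alert catalog(s): {sorted(unknown)}")
    mol = _mol_from_record(record)
    hits: list[tuple[str, str]] = []
    for name in KNOWN_CATALOGS:  # fixed order for determinism
        if name not in catalogs:
            continue
        for entry in _catalog(name).GetMatches(mol):
            hits.append((name, entry.GetDescription()))
    return hits


def compute_descriptors(record: CompoundRecord) -> DescriptorSet:
    """Full descriptor set for one compound; raises on unparseable structures."""
    mol = _mol_from_record(record)
    mol_h = Chem.AddHs(mol)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        molar_refractivity=Crippen.MolMR(mol),
        atom_count=mol_h.GetNumAtoms(),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        qed_raw=QED.qed(mol),
        sa_raw=sascorer.calculateScore(mol),
        alerts=tuple(detect_alerts(record)),
    )


def descriptor_table(records: list[CompoundRecord]):
    """Descriptor table as a pandas DataFrame, one row per compound."""
    import pandas as pd

    rows = []
    for rec in records:
        d = compute_descriptors(rec)
        rows.append(
            {
                "identifier": rec.identifier,
                "mw": d.mw,
                "logp": d.logp,
                "hbd": d.hbd,
                "hba": d.hba,
                "rotb": d.rotb,
                "tpsa": d.tpsa,
                "molar_refractivity": d.molar_refractivity,
                "atom_count": d.atom_count,
                "heavy_atoms": d.heavy_atoms,
                "aromatic_rings": d.aromatic_rings,
                "qed_raw": d.qed_raw,
                "sa_raw": d.sa_raw,
                "n_alerts": len(d.alerts),
            }
        )
    return pd.DataFrame(rows)
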