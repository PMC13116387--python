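"""Co-crystal ligand geometry: PDB parsing, structure screening, docking boxes, RMSD.

The docking search volume is derived from the co-crystallized ("eutectic")
ligand's axis-aligned bounding box:

    center = (max + min) / 2            per axis
    size   = (max − min) + 2δ           per axis, δ = 4.0 Å padding

Pose validation is the raw root-mean-square deviation between corresponding
atom coordinates in the shared docking frame (no superposition, no symmetry
correction); a redocked pose passes when RMSD ≤ 2.0 Å.  Receptor structures
are screened for Homo sapiens origin, X-ray resolution < 3.0 Å, a single
chain, and a co-crystal ligand of ≥ 100 Da.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

DEFAULT_PADDING = 4.0  # Å
DEFAULT_REDOCK_THRESHOLD = 2.0  # Å
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    record_kind: str  # "ATOM" | "HETATM"
    serial: int
    atom_name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: tuple[float, float, float]
    occupancy: float
    element: str


@dataclass(frozen=True)
class StructureMetadata:
    pdb_id: Optional[str] = None
    experimental_method: Optional[str] = None
    resolution: Optional[float] = None  # Å; None = unknown
    chain_count: Optional[int] = None
    ligand_mw: Optional[float] = None  # Da
    organism: Optional[str] = None


@dataclass(frozen=True)
class LigandCoordinates:
    """Ordered ligand atom coordinates; ordering is the RMSD correspondence."""

    coords: tuple[tuple[float, float, float], ...]
    residue_name: str
    structure_id: str = ""

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    padding: float


@dataclass(frozen=True)
class ScreeningCriteria:
    organism: str = "Homo sapiens"
    max_resolution: float = 3.0  # strict: resolution must be < this
    required_chains: int = 1
    min_ligand_mw: float = 100.0  # inclusive


def read_pdb(text: str) -> tuple[list[AtomRecord], StructureMetadata]:
    """Fixed-column parse of PDB text.

    Alternate locations collapse to one atom per (chain, residue, atom name):
    blank altloc wins, otherwise the highest-occupancy record (first on tie,
    which keeps 'A' under the usual file ordering).  Header metadata is taken
    from HEADER/EXPDTA/REMARK 2/SOURCE when present, else left unknown.
    """
    atoms: list[AtomRecord] = []
    chosen: dict[tuple[str, int, str, str], int] = {}  # key -> index in atoms
    pdb_id = method = organism = None
    resolution = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, rec)
            key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.atom_name)
            if key in chosen:
                prev = atoms[chosen[key]]
                if _altloc_rank(atom) > _altloc_rank(prev):
                    atoms[chosen[key]] = atom
            else:
                chosen[key] = len(atoms)
                atoms.append(atom)
        elif rec == "HEADER":
            tail = line[62:66].strip()
            pdb_id = tail if tail else pdb_id
        elif rec == "EXPDTA":
            method = line[10:].strip() or method
        elif rec == "REMARK" and line[7:10].strip() == "2":
            resolution = _parse_resolution(line)  # may stay None
        elif rec == "SOURCE" and "ORGANISM_SCIENTIFIC" in line:
            organism = line.split(":", 1)[1].strip().rstrip(";").rstrip(".")
    if not atoms:
        raise ValueError("no ATOM/HETATM records in PDB text")
    chain_ids = {a.chain_id for a in atoms if a.record_kind == "ATOM"}
    meta = StructureMetadata(
        pdb_id=pdb_id,
        experimental_method=method,
        resolution=resolution,
        chain_count=len(chain_ids) if chain_ids else None,
        organism=organism,
    )
    return atoms, meta


def _parse_atom_line(line: str, kind: str) -> AtomRecord:
    line = line.ljust(80)
    try:
        occupancy = float(line[54:60])
    except ValueError:
        occupancy = 1.0
    element = line[76:78].strip()
    if not element:
        # fall back to the first alphabetic character of the atom name
        element = next((c for c in line[12:16].strip() if c.isalpha()), "X").upper()
    return AtomRecord(
        record_kind=kind,
        serial=int(line[6:11]),
        atom_name=line[12:16].strip(),
        altloc=line[16].strip(),
        residue_name=line[17:20].strip(),
        chain_id=line[21].strip(),
        residue_number=int(line[22:26]),
        coords=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
        occupancy=occupancy,
        element=element,
    )


def _altloc_rank(atom: AtomRecord) -> tuple[int, float]:
    return (1 if atom.altloc == "" else 0, atom.occupancy)


def _parse_resolution(line: str) -> Optional[float]:
    if "RESOLUTION" not in line:
        return None
    tail = line.split("RESOLUTION", 1)[1]
    for token in tail.replace("ANGSTROMS", " ").split():
        try:
            return float(token)
        except ValueError:
            continue
    return None


def extract_ligand(atoms: Sequence[AtomRecord], residue_name: str) -> LigandCoordinates:
    """All HETATM atoms of the first (chain, residue-number) instance of ``residue_name``.

    Water residues are refused; file order is preserved because it defines
    the atom correspondence used by :func:`compute_rmsd`.
    """
    resname = residue_name.strip().upper()
    if resname in WATER_RESIDUES:
        raise ValueError(f"{resname} is solvent, not a ligand")
    instance: Optional[tuple[str, int]] = None
    coords: list[tuple[float, float, float]] = []
    for atom in atoms:
        if atom.record_kind != "HETATM" or atom.residue_name != resname:
            continue
        key = (atom.chain_id, atom.residue_number)
        if instance is None:
            instance = key
        if key == instance:
            coords.append(atom.coords)
    if instance is None:
        raise ValueError(f"no HETATM residue {resname!r} in structure")
    return LigandCoordinates(tuple(coords), resname)


def screen_structure(
    meta: StructureMetadata, criteria: ScreeningCriteria = ScreeningCriteria()
) -> tuple[bool, list[str]]:
    """Accept iff all four screening criteria hold; unknown fields fail closed."""
    reasons: list[str] = []
    if meta.organism is None:
        reasons.append("unknown-field:organism")
    elif meta.organism.strip().lower() != criteria.organism.lower():
        reasons.append(f"organism {meta.organism!r} != {criteria.organism!r}")
    method_ok = meta.experimental_method and "X-RAY" in meta.experimental_method.upper()
    if meta.resolution is None:
        reasons.append("unknown-field:resolution")
    elif not method_ok:
        reasons.append(f"method {meta.experimental_method!r} is not X-ray diffraction")
    elif meta.resolution >= criteria.max_resolution:
        reasons.append(
            f"resolution {meta.resolution} Å not < {criteria.max_resolution} Å"
        )
    if meta.chain_count is None:
        reasons.append("unknown-field:chain_count")
    elif meta.chain_count != criteria.required_chains:
        reasons.append(f"{meta.chain_count} chains != {criteria.required_chains}")
    if meta.ligand_mw is None:
        reasons.append("unknown-field:ligand_mw")
    elif meta.ligand_mw < criteria.min_ligand_mw:
        reasons.append(
            f"ligand MW {meta.ligand_mw} Da < {criteria.min_ligand_mw} Da"
        )
    return (not reasons, reasons)


def compute_box(lig: LigandCoordinates, padding: float = DEFAULT_PADDING) -> DockingBox:
    """Axis-aligned bounding box of the ligand, grown by ``padding`` per face."""
    if len(lig) == 0:
        raise ValueError("cannot build a docking box from empty coordinates")
    if padding < 0:
        raise ValueError(f"padding must be non-negative, got {padding}")
    lo = [min(c[i] for c in lig.coords) for i in range(3)]
    hi = [max(c[i] for c in lig.coords) for i in range(3)]
    center = tuple((hi[i] + lo[i]) / 2.0 for i in range(3))
    size = tuple((hi[i] - lo[i]) + 2.0 * padding for i in range(3))
    return DockingBox(center, size, padding)


def compute_rmsd(a: LigandCoordinates, b: LigandCoordinates) -> float:
    """Raw coordinate RMSD over the ordered atom correspondence (Å)."""
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty coordinate lists")
    sq = math.fsum(
        (pa[i] - pb[i]) ** 2 for pa, pb in zip(a.coords, b.coords) for i in range(3)
    )
    return math.sqrt(sq / len(a))


def redock_check(rmsd: float, threshold: float = DEFAULT_REDOCK_THRESHOLD) -> bool:
    """Pose validation: pass when RMSD ≤ threshold (inclusive)."""
    if rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    return rmsd <= threshold


def box_to_json(box: DockingBox) -> str:
    return json.dumps(
        {
            "center": dict(zip("xyz", box.center)),
            "size": dict(zip("xyz", box.size)),
            "padding": box.padding,
        },
        indent=2,
    )


def box_to_vina_config(box: DockingBox) -> str:
    """Vina-style config text block (center_x … size_z keys)."""
    lines = [f"center_{ax} = {v:.3f}" for ax, v in zip("xyz", box.center)]
    lines += [f"size_{ax} = {v:.3f}" for ax, v in zip("xyz", box.size)]
    return "\n".join(lines) + "\n"
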