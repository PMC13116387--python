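"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their spec (seed included):

* compound libraries sampled from a curated SMILES panel, stratified at run
  time by the default drug-likeness scorer so a target grade mix can be
  requested (emulating a drug-signature enrichment hit list of ~171
  small molecules);
* toy protein–ligand complexes whose PDB text contains exactly the planted
  hydrogen-bond / salt-bridge / hydrophobic / π contacts, with every
  non-planted pair kept at least 0.5 Å beyond the widest cutoff;
* scale-free PPI-like networks (preferential attachment) with STRING-style
  edge scores and an optional planted hub wired to a set fraction of nodes.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .compound_io import CompoundRecord
from .druglikeness import GRADES, WeightVector, score_compound
from .interactions import DEFAULT_CUTOFFS

#: Grade mix used when none is requested: the distribution a realistic
#: enrichment-derived screening library shows (mostly good-but-not-excellent).
DEFAULT_GRADE_MIX = {"A": 25 / 171, "B": 92 / 171, "C": 37 / 171, "D": 10 / 171, "F": 7 / 171}

CLEARANCE = 0.5  # Å beyond the widest cutoff for all non-planted pairs
INSIDE_MARGIN = 0.1  # Å inside the cutoff for planted distances


@dataclass(frozen=True)
class LibrarySpec:
    n: int = 171
    grade_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GRADE_MIX))
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("library size must be >= 1")
        total = sum(self.grade_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"grade-mix proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class ComplexSpec:
    pocket_atoms: int = 40
    n_hbond: int = 2
    n_salt: int = 1
    n_hydrophobic: int = 2
    n_pi: int = 1
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_hbond, self.n_salt, self.n_hydrophobic, self.n_pi)
        if any(c < 0 for c in counts):
            raise ValueError("planted contact counts must be >= 0")
        if sum(counts) > 12:
            raise ValueError("at most 12 planted contacts are geometrically supported")


@dataclass(frozen=True)
class NetworkSpec:
    n: int = 311
    attachment: int = 3
    planted_hub: bool = True
    hub_fraction: float = 0.30
    frac_below_threshold: float = 0.40
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("network needs at least 2 nodes")
        if not 0 <= self.frac_below_threshold <= 1:
            raise ValueError("frac_below_threshold must be in [0, 1]")


# ---------------------------------------------------------------------------
# compound libraries


def load_panel() -> list[CompoundRecord]:
    """The curated SMILES panel shipped with the package."""
    text = resources.files("gradescreen").joinpath("data/smiles_panel.csv").read_text()
    reader = csv.DictReader(io.StringIO(text))
    return [
        CompoundRecord(row["identifier"], row["name"], row["smiles"], source="panel")
        for row in reader
    ]


_PANEL_STRATA: Optional[dict[str, list[CompoundRecord]]] = None


def panel_strata() -> dict[str, list[CompoundRecord]]:
    """Panel compounds bucketed by grade under the default scorer (cached)."""
    global _PANEL_STRATA
    if _PANEL_STRATA is None:
        strata: dict[str, list[CompoundRecord]] = {g: [] for g in GRADES}
        for rec in load_panel():
            strata[score_compound(rec, WeightVector()).grade].append(rec)
        _PANEL_STRATA = strata
    return _PANEL_STRATA


def generate_compound_library(spec: LibrarySpec) -> list[CompoundRecord]:
    """Sample ``spec.n`` compounds approximating the target grade mix.

    Within-stratum sampling is with replacement (the panel is finite), so a
    large library contains repeated structures under fresh identifiers —
    downstream deduplication is exercised separately on purpose-built
    fixtures, not on these libraries.
    """
    spec.validate()
    strata = panel_strata()
    for grade, prop in spec.grade_mix.items():
        if prop > 0 and not strata.get(grade):
            raise ValueError(f"grade-{grade} stratum of the panel is empty")
    rng = np.random.default_rng(spec.seed)
    # largest-remainder apportionment of n over the grades
    quotas = {g: spec.n * p for g, p in spec.grade_mix.items()}
    counts = {g: int(math.floor(q)) for g, q in quotas.items()}
    short = spec.n - sum(counts.values())
    for g in sorted(quotas, key=lambda g: (counts[g] - quotas[g], g))[:short]:
        counts[g] += 1
    out: list[CompoundRecord] = []
    for grade in GRADES:
        k = counts.get(grade, 0)
        if k == 0:
            continue
        pool = strata[grade]
        for idx in rng.integers(0, len(pool), size=k):
            src = pool[int(idx)]
            out.append(
                CompoundRecord(
                    identifier=f"cmpd_{len(out) + 1:04d}",
                    name=src.name,
                    smiles=src.smiles,
                    source="synthetic",
                )
            )
    return out


# ---------------------------------------------------------------------------
# toy complexes

# 12 icosahedron vertex directions: pairwise angle >= 63.4 degrees
_PHI = (1 + math.sqrt(5)) / 2
_DIRECTIONS = [
    np.array(v) / np.linalg.norm(v)
    for v in [
        (0, 1, _PHI), (0, -1, _PHI), (0, 1, -_PHI), (0, -1, -_PHI),
        (1, _PHI, 0), (-1, _PHI, 0), (1, -_PHI, 0), (-1, -_PHI, 0),
        (_PHI, 0, 1), (-_PHI, 0, 1), (_PHI, 0, -1), (-_PHI, 0, -1),
    ]
]

_LIGAND_RADIUS = 6.0  # Å from origin to each planted ligand atom
_FILLER_RADIUS = 14.0  # Å; far enough that filler never contacts the ligand

#: planted distance windows per kind, chosen so a planted pair satisfies its
#: own cutoff but no other kind's criteria (salt bridges stay > 3.5 + 0.5 Å
#: so they never double as hydrogen bonds)
_DISTANCE_WINDOWS = {
    "hydrogen-bond": (2.7, DEFAULT_CUTOFFS["hydrogen-bond"] - INSIDE_MARGIN),
    "salt-bridge": (DEFAULT_CUTOFFS["hydrogen-bond"] + CLEARANCE + INSIDE_MARGIN,
                    DEFAULT_CUTOFFS["salt-bridge"] - INSIDE_MARGIN),
    "hydrophobic": (3.2, DEFAULT_CUTOFFS["hydrophobic"] - INSIDE_MARGIN),
    "pi": (4.2, DEFAULT_CUTOFFS["pi"] - INSIDE_MARGIN),
}


@dataclass(frozen=True)
class PlantedContact:
    kind: str
    ligand_atom: int  # index within the extracted ligand atom list
    protein_residue: str
    distance: float


def _pdb_line(
    kind: str, serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: np.ndarray, element: str,
) -> str:
    return (
        f"{kind:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain}{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{element:>2}"
    )


def _hexagon(center: np.ndarray, axis: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    """Six points of a regular hexagon in the plane perpendicular to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(axis @ helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return [
        center + radius * (math.cos(a) * u + math.sin(a) * v)
        for a in (k * math.pi / 3 for k in range(6))
    ]


def generate_toy_complex(spec: ComplexSpec) -> tuple[str, list[PlantedContact]]:
    """PDB text of a pseudo pocket plus ligand, with exact planted contacts.

    Each planted contact occupies its own icosahedral ray from the origin:
    the ligand atom (or ring centroid) sits 6 Å out, its protein partner at
    6 Å + the planted distance.  Cross-ray ligand–protein separations are
    then ≥ 6 Å > widest cutoff + 0.5 Å, and inert filler atoms sit on a
    14 Å shell, so exactly the planted pairs satisfy the cutoffs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plan = (
        ["hydrogen-bond"] * spec.n_hbond
        + ["salt-bridge"] * spec.n_salt
        + ["hydrophobic"] * spec.n_hydrophobic
        + ["pi"] * spec.n_pi
    )
    dirs = [_DIRECTIONS[i] for i in rng.permutation(12)[: len(plan)]]

    lig_lines: list[tuple[str, str, np.ndarray]] = []  # (atom name, element, xyz)
    prot_lines: list[tuple[str, str, str, np.ndarray]] = []  # (name, resname, elem, xyz)
    truth: list[PlantedContact] = []

    for kind, d in zip(plan, dirs):
        lo, hi = _DISTANCE_WINDOWS[kind]
        dist = float(rng.uniform(lo, hi))
        lig_pos = _LIGAND_RADIUS * d
        prot_pos = (_LIGAND_RADIUS + dist) * d
        if kind == "hydrogen-bond":
            lig_idx = len(lig_lines)
            lig_lines.append((f"O{lig_idx + 1}", "O", lig_pos))
            prot_lines.append(("N", "GLY", "N", prot_pos))
        elif kind == "salt-bridge":
            lig_idx = len(lig_lines)
            lig_lines.append((f"N{lig_idx + 1}", "N", lig_pos))
            prot_lines.append(("OD1", "ASP", "O", prot_pos))
        elif kind == "hydrophobic":
            lig_idx = len(lig_lines)
            lig_lines.append((f"C{lig_idx + 1}", "C", lig_pos))
            prot_lines.append(("CD1", "LEU", "C", prot_pos))
        else:  # pi: ligand benzene ring vs PHE ring, centroid-to-centroid
            lig_idx = len(lig_lines)
            for k, p in enumerate(_hexagon(lig_pos, d)):
                lig_lines.append((f"C{lig_idx + k + 1}", "C", p))
            ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
            for name, p in zip(ring_names, _hexagon(prot_pos, d)):
                prot_lines.append((name, "PHE", "C", p))
        resnum = len(truth) + 1
        resname = {"hydrogen-bond": "GLY", "salt-bridge": "ASP",
                   "hydrophobic": "LEU", "pi": "PHE"}[kind]
        truth.append(PlantedContact(kind, lig_idx, f"{resname}{resnum}:A", dist))

    # scaffold carbon at the origin: keeps the ligand non-empty (boxes need
    # >= 1 atom) and sits >= 8 Å from every planted protein partner
    lig_lines.append((f"C{len(lig_lines) + 1}", "C", np.zeros(3)))

    # inert filler: GLY CA carbons on a far shell (CA carries no roles)
    n_filler = max(0, spec.pocket_atoms - len(prot_lines))
    for _ in range(n_filler):
        v = rng.normal(size=3)
        v = _FILLER_RADIUS * v / np.linalg.norm(v)
        prot_lines.append(("CA", "GLY", "C", v))

    lines: list[str] = ["HEADER    SYNTHETIC TOY COMPLEX"]
    serial = 1
    # protein atoms: planted partners keep one residue per planted contact,
    # numbered in plant order; filler residues continue the numbering
    resnum = 0
    planted_partner_count = len(prot_lines) - n_filler
    for i, (name, resname, elem, xyz) in enumerate(prot_lines):
        if i >= planted_partner_count or resname != "PHE" or name == "CG":
            resnum += 1
        lines.append(_pdb_line("ATOM", serial, name, resname, "A", resnum, xyz, elem))
        serial += 1
    lines.append("TER")
    for name, elem, xyz in lig_lines:
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "B", 900, xyz, elem))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# PPI-like networks


def generate_ppi_network(spec: NetworkSpec) -> tuple[str, Optional[str]]:
    """STRING-style TSV edge list; returns (tsv text, planted hub symbol).

    Preferential-attachment backbone; edge scores drawn so that
    ``frac_below_threshold`` of backbone edges fall below 400 (uniform on
    [150, 399] vs [400, 999]); the optional hub connects to
    ``hub_fraction`` of the other nodes with high-confidence scores.
    """
    import networkx as nx

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = nx.barabasi_albert_graph(
        spec.n, min(spec.attachment, spec.n - 1), seed=int(rng.integers(0, 2**31))
    )
    label = {i: f"G{i + 1:04d}" for i in g.nodes()}
    rows: list[tuple[str, str, int]] = []
    for u, v in g.edges():
        low = rng.random() < spec.frac_below_threshold
        score = int(rng.integers(150, 400)) if low else int(rng.integers(400, 1000))
        a, b = sorted((label[u], label[v]))
        rows.append((a, b, score))
    hub = None
    if spec.planted_hub:
        hub = "HUB0001"
        k = max(1, int(round(spec.hub_fraction * spec.n)))
        targets = rng.choice(spec.n, size=k, replace=False)
        for t in targets:
            a, b = sorted((hub, label[int(t)]))
            rows.append((a, b, int(rng.integers(700, 1000))))
    rows.sort()
    out = ["geneA\tgeneB\tcombined_score"]
    out += [f"{a}\t{b}\t{s}" for a, b, s in rows]
    return "\n".join(out) + "\n", hub
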