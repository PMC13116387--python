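"""Distance-cutoff typing of protein–ligand contacts.

Contacts are classified from heavy-atom geometry alone, PLIP-style but
distance-only (no donor–H–acceptor or ring-plane angle terms):

* hydrogen bond — donor ↔ acceptor pair ≤ 3.5 Å
* salt bridge   — cation ↔ anion pair ≤ 5.5 Å
* hydrophobic   — apolar carbon ↔ apolar carbon ≤ 4.0 Å
* π interaction — aromatic ring centroid ↔ centroid, or centroid ↔ cation, ≤ 5.5 Å

Protein atoms get their roles from a residue/atom-name template shipped with
the package; ligand atoms are typed from inferred connectivity (bonds =
heavy-atom pairs within 1.9 Å).  Aromatic carbons participate through the
π channel only — they are not additionally counted as hydrophobic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .docking_geometry import AtomRecord, WATER_RESIDUES

DEFAULT_CUTOFFS = {
    "hydrogen-bond": 3.5,
    "salt-bridge": 5.5,
    "hydrophobic": 4.0,
    "pi": 5.5,
}

COVALENT_CUTOFF = 1.9  # Å heavy-atom bond inference

Coords = tuple[float, float, float]


@dataclass(frozen=True)
class TypedAtom:
    source: str  # "ligand" | "protein"
    index: int  # position within its source list
    coords: Coords
    roles: frozenset[str]
    residue: str = ""  # "NAME<number>:<chain>" descriptor
    ring_id: Optional[str] = None


@dataclass(frozen=True)
class Contact:
    kind: str
    ligand_atom: int
    protein_residue: str
    distance: float


def _dist(a: Coords, b: Coords) -> float:
    return math.dist(a, b)


# ---------------------------------------------------------------------------
# role perception


def _load_protein_role_table() -> dict[tuple[str, str], frozenset[str]]:
    table: dict[tuple[str, str], frozenset[str]] = {}
    text = (
        resources.files("gradescreen").joinpath("data/protein_atom_roles.tsv").read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("resname\t"):
            continue
        parts = line.split("\t")
        resname, atom_name = parts[0], parts[1]
        roles = (
            frozenset(parts[2].split(",")) if len(parts) > 2 and parts[2] else frozenset()
        )
        table[(resname, atom_name)] = roles
    return table


_PROTEIN_ROLES: Optional[dict[tuple[str, str], frozenset[str]]] = None


def _protein_roles() -> dict[tuple[str, str], frozenset[str]]:
    global _PROTEIN_ROLES
    if _PROTEIN_ROLES is None:
        _PROTEIN_ROLES = _load_protein_role_table()
    return _PROTEIN_ROLES


def _residue_descriptor(atom: AtomRecord) -> str:
    return f"{atom.residue_name}{atom.residue_number}:{atom.chain_id or '_'}"


def type_protein_atoms(atoms: Sequence[AtomRecord]) -> list[TypedAtom]:
    """Assign roles to protein atoms from the residue/atom-name template.

    Atoms of aromatic residues carrying the ring role are grouped into one
    ring per residue instance (ring id = residue descriptor).
    """
    table = _protein_roles()
    typed: list[TypedAtom] = []
    for i, atom in enumerate(atoms):
        if atom.residue_name in WATER_RESIDUES:
            continue
        roles = table.get((atom.residue_name, atom.atom_name))
        if roles is None:
            roles = table.get(("*", atom.atom_name), frozenset())
        ring_id = None
        if "ring" in roles:
            ring_id = _residue_descriptor(atom)
            roles = roles - {"ring"} | {"aromatic-ring-member"}
        typed.append(
            TypedAtom(
                source="protein",
                index=i,
                coords=atom.coords,
                roles=frozenset(roles),
                residue=_residue_descriptor(atom),
                ring_id=ring_id,
            )
        )
    return typed


def type_ligand_atoms(atoms: Sequence[AtomRecord]) -> list[TypedAtom]:
    """Assign roles to ligand heavy atoms from inferred connectivity.

    Rules (documented simplifications for hydrogen-free coordinates):
    nitrogen → donor + acceptor, and cation when all neighbours are carbon
    (amine-like); oxygen → acceptor, plus donor when terminal (hydroxyl-like)
    unless part of a carboxylate, whose oxygens are anions; carbon with no
    N/O neighbour → hydrophobic; atoms of 5–6-membered C/N rings →
    aromatic-ring-member (one ring id per ring).
    """
    import networkx as nx

    n = len(atoms)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if _dist(atoms[i].coords, atoms[j].coords) <= COVALENT_CUTOFF:
                g.add_edge(i, j)

    elem = [a.element.upper() for a in atoms]
    rings = [
        cyc
        for cyc in nx.cycle_basis(g)
        if len(cyc) in (5, 6) and all(elem[i] in ("C", "N") for i in cyc)
    ]
    ring_of: dict[int, str] = {}
    for k, cyc in enumerate(rings):
        for i in cyc:
            ring_of.setdefault(i, f"lig-ring-{k}")

    carboxylate_o: set[int] = set()
    for i in range(n):
        if elem[i] != "C":
            continue
        terminal_o = [
            j for j in g.neighbors(i) if elem[j] == "O" and g.degree(j) == 1
        ]
        if len(terminal_o) >= 2:
            carboxylate_o.update(terminal_o)

    typed: list[TypedAtom] = []
    for i, atom in enumerate(atoms):
        roles: set[str] = set()
        nbr_elems = [elem[j] for j in g.neighbors(i)]
        e = elem[i]
        if e == "N":
            roles |= {"donor", "acceptor"}
            if all(x == "C" for x in nbr_elems) and i not in ring_of:
                roles.add("cation")
        elif e == "O":
            roles.add("acceptor")
            if i in carboxylate_o:
                roles.add("anion")
            elif g.degree(i) <= 1:
                roles.add("donor")
        elif e == "C":
            if i in ring_of:
                pass  # aromatic carbons act through the π channel only
            elif not any(x in ("N", "O") for x in nbr_elems):
                roles.add("hydrophobic")
        if i in ring_of:
            roles.add("aromatic-ring-member")
        typed.append(
            TypedAtom(
                source="ligand",
                index=i,
                coords=atom.coords,
                roles=frozenset(roles),
                residue=_residue_descriptor(atom),
                ring_id=ring_of.get(i),
            )
        )
    return typed


def type_atoms(atoms: Sequence[AtomRecord], molecule: str) -> list[TypedAtom]:
    """Role perception dispatcher; ``molecule`` is "protein" or "ligand"."""
    if molecule == "protein":
        return type_protein_atoms(atoms)
    if molecule == "ligand":
        return type_ligand_atoms(atoms)
    raise ValueError(f"molecule context must be 'protein' or 'ligand', got {molecule!r}")


# ---------------------------------------------------------------------------
# contact detection


def _ring_centroids(atoms: Iterable[TypedAtom]) -> dict[str, tuple[Coords, int, str]]:
    """ring id -> (centroid, representative atom index, residue descriptor)."""
    groups: dict[str, list[TypedAtom]] = {}
    for a in atoms:
        if a.ring_id is not None:
            groups.setdefault(a.ring_id, []).append(a)
    out: dict[str, tuple[Coords, int, str]] = {}
    for rid, members in groups.items():
        cx = sum(m.coords[0] for m in members) / len(members)
        cy = sum(m.coords[1] for m in members) / len(members)
        cz = sum(m.coords[2] for m in members) / len(members)
        rep = min(members, key=lambda m: m.index)
        out[rid] = ((cx, cy, cz), rep.index, rep.residue)
    return out


def find_contacts(
    ligand: Sequence[TypedAtom],
    protein: Sequence[TypedAtom],
    cutoffs: dict[str, float] | None = None,
) -> list[Contact]:
    """All typed contacts between ligand and protein atoms.

    Atom–atom kinds (hydrogen bond, salt bridge, hydrophobic) report each
    qualifying pair once; π contacts are evaluated between ring centroids
    and between centroids and cations.
    """
    if not ligand or not protein:
        raise ValueError("ligand and protein atom lists must be non-empty")
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)

    contacts: list[Contact] = []
    for la in ligand:
        for pa in protein:
            d = _dist(la.coords, pa.coords)
            if d <= cut["hydrogen-bond"] and (
                ("donor" in la.roles and "acceptor" in pa.roles)
                or ("acceptor" in la.roles and "donor" in pa.roles)
            ):
                contacts.append(Contact("hydrogen-bond", la.index, pa.residue, d))
            if d <= cut["salt-bridge"] and (
                ("cation" in la.roles and "anion" in pa.roles)
                or ("anion" in la.roles and "cation" in pa.roles)
            ):
                contacts.append(Contact("salt-bridge", la.index, pa.residue, d))
            if (
                d <= cut["hydrophobic"]
                and "hydrophobic" in la.roles
                and "hydrophobic" in pa.roles
            ):
                contacts.append(Contact("hydrophobic", la.index, pa.residue, d))

    lig_rings = _ring_centroids(ligand)
    prot_rings = _ring_centroids(protein)
    for lc, lrep, _ in lig_rings.values():
        for pc, _, pres in prot_rings.values():
            d = _dist(lc, pc)
            if d <= cut["pi"]:
                contacts.append(Contact("pi", lrep, pres, d))
        for pa in protein:
            if "cation" in pa.roles:
                d = _dist(lc, pa.coords)
                if d <= cut["pi"]:
                    contacts.append(Contact("pi", lrep, pa.residue, d))
    for la in ligand:
        if "cation" in la.roles:
            for pc, _, pres in prot_rings.values():
                d = _dist(la.coords, pc)
                if d <= cut["pi"]:
                    contacts.append(Contact("pi", la.index, pres, d))
    return contacts


def summarize_contacts(contacts: Sequence[Contact]):
    """Per-residue, per-kind contact table with minimum distance per group.

    Rows are ordered by residue number (parsed from the descriptor), then
    residue, then kind.  Returns a pandas DataFrame.
    """
    import pandas as pd

    groups: dict[tuple[str, str], list[float]] = {}
    for c in contacts:
        groups.setdefault((c.protein_residue, c.kind), []).append(c.distance)

    def resnum(descriptor: str) -> int:
        digits = "".join(ch for ch in descriptor.split(":")[0] if ch.isdigit())
        return int(digits) if digits else 0

    rows = [
        {
            "residue": res,
            "kind": kind,
            "n_contacts": len(ds),
            "min_distance": min(ds),
        }
        for (res, kind), ds in groups.items()
    ]
    rows.sort(key=lambda r: (resnum(r["residue"]), r["residue"], r["kind"]))
    return pd.DataFrame(rows, columns=["residue", "kind", "n_contacts", "min_distance"])
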