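import math

import pytest

from gradescreen.docking_geometry import read_pdb
from gradescreen.interactions import (
    DEFAULT_CUTOFFS,
    find_contacts,
    summarize_contacts,
    type_atoms,
)
from gradescreen.synthetic_data import ComplexSpec, generate_toy_complex

from test_docking_geometry import pdb_atom


def split_complex(pdb_text):
    atoms, _ = read_pdb(pdb_text)
    ligand = [a for a in atoms if a.record_kind == "HETATM"]
    protein = [a for a in atoms if a.record_kind == "ATOM"]
    return type_atoms(ligand, "ligand"), type_atoms(protein, "protein")


def brute_force_contacts(ligand, protein, cutoffs=DEFAULT_CUTOFFS):
    """Naive all-pairs rescan, written independently of find_contacts."""
    found = set()
    for la in ligand:
        for pa in protein:
            d = math.dist(la.coords, pa.coords)
            pairs = {(r1, r2) for r1 in la.roles for r2 in pa.roles}
            if d <= cutoffs["hydrogen-bond"] and (
                ("donor", "acceptor") in pairs or ("acceptor", "donor") in pairs
            ):
                found.add(("hydrogen-bond", la.index, pa.residue))
            if d <= cutoffs["salt-bridge"] and (
                ("cation", "anion") in pairs or ("anion", "cation") in pairs
            ):
                found.add(("salt-bridge", la.index, pa.residue))
            if d <= cutoffs["hydrophobic"] and ("hydrophobic", "hydrophobic") in pairs:
                found.add(("hydrophobic", la.index, pa.residue))

    def centroids(atoms):
        rings = {}
        for a in atoms:
            if a.ring_id:
                rings.setdefault(a.ring_id, []).append(a)
        return {
            rid: (
                tuple(sum(m.coords[i] for m in ms) / len(ms) for i in range(3)),
                min(m.index for m in ms),
                min(ms, key=lambda m: m.index).residue,
            )
            for rid, ms in rings.items()
        }

    lrings, prings = centroids(ligand), centroids(protein)
    for lc, lidx, _ in lrings.values():
        for pc, _, pres in prings.values():
            if math.dist(lc, pc) <= cutoffs["pi"]:
                found.add(("pi", lidx, pres))
        for pa in protein:
            if "cation" in pa.roles and math.dist(lc, pa.coords) <= cutoffs["pi"]:
                found.add(("pi", lidx, pa.residue))
    for la in ligand:
        if "cation" in la.roles:
            for pc, _, pres in prings.values():
                if math.dist(la.coords, pc) <= cutoffs["pi"]:
                    found.add(("pi", la.index, pres))
    return found


class TestTypeAtoms:
    def test_protein_textbook_roles(self):
        text = "\n".join([
            pdb_atom("ATOM", 1, "N", "GLY", "A", 1, 0, 0, 0, element="N"),
            pdb_atom("ATOM", 2, "O", "GLY", "A", 1, 1, 0, 0, element="O"),
            pdb_atom("ATOM", 3, "NZ", "LYS", "A", 2, 2, 0, 0, element="N"),
            pdb_atom("ATOM", 4, "OD1", "ASP", "A", 3, 3, 0, 0, element="O"),
            pdb_atom("ATOM", 5, "CD1", "LEU", "A", 4, 4, 0, 0, element="C"),
            pdb_atom("ATOM", 6, "N", "PRO", "A", 5, 5, 0, 0, element="N"),
        ])
        atoms, _ = read_pdb(text)
        typed = type_atoms(atoms, "protein")
        assert typed[0].roles == frozenset({"donor"})  # backbone N
        assert typed[1].roles == frozenset({"acceptor"})  # backbone O
        assert typed[2].roles == frozenset({"donor", "cation"})  # LYS NZ
        assert "anion" in typed[3].roles and "acceptor" in typed[3].roles
        assert typed[4].roles == frozenset({"hydrophobic"})
        assert typed[5].roles == frozenset()  # proline backbone N: no H to donate

    def test_ligand_hydroxyl_oxygen_donor_acceptor(self):
        text = "\n".join([
            pdb_atom("HETATM", 1, "C1", "LIG", "A", 1, 0.0, 0, 0, element="C"),
            pdb_atom("HETATM", 2, "O1", "LIG", "A", 1, 1.4, 0, 0, element="O"),
        ])
        atoms, _ = read_pdb(text)
        typed = type_atoms(atoms, "ligand")
        assert typed[1].roles == frozenset({"donor", "acceptor"})
        # the carbon is bonded to O, so it is not hydrophobic
        assert "hydrophobic" not in typed[0].roles

    def test_ligand_aliphatic_carbon_hydrophobic(self):
        atoms, _ = read_pdb(pdb_atom("HETATM", 1, "C1", "LIG", "A", 1, 0, 0, 0, element="C"))
        assert type_atoms(atoms, "ligand")[0].roles == frozenset({"hydrophobic"})

    def test_benzene_ring_centroid_at_ring_center(self):
        center = (3.0, -1.0, 2.0)
        coords = [
            (center[0] + 1.39 * math.cos(k * math.pi / 3),
             center[1] + 1.39 * math.sin(k * math.pi / 3), center[2])
            for k in range(6)
        ]
        text = "\n".join(
            pdb_atom("HETATM", i + 1, f"C{i+1}", "LIG", "A", 1, *c, element="C")
            for i, c in enumerate(coords)
        )
        atoms, _ = read_pdb(text)
        typed = type_atoms(atoms, "ligand")
        assert all("aromatic-ring-member" in a.roles for a in typed)
        assert len({a.ring_id for a in typed}) == 1
        from gradescreen.interactions import _ring_centroids

        (centroid, _, _), = _ring_centroids(typed).values()
        assert centroid == pytest.approx(center, abs=1e-9)

    def test_unknown_molecule_context_rejected(self):
        with pytest.raises(ValueError):
            type_atoms([], "rna")


class TestFindContacts:
    def _pair(self, lig_spec, prot_spec, distance):
        lname, lelem = lig_spec
        pname, presname, pelem = prot_spec
        text = "\n".join([
            pdb_atom("ATOM", 1, pname, presname, "A", 1, distance, 0, 0, element=pelem),
            pdb_atom("HETATM", 2, lname, "LIG", "B", 9, 0, 0, 0, element=lelem),
        ])
        return split_complex(text)

    def test_donor_acceptor_at_3_4_is_a_hydrogen_bond(self):
        lig, prot = self._pair(("O1", "O"), ("N", "GLY", "N"), 3.4)
        contacts = find_contacts(lig, prot)
        assert [c.kind for c in contacts] == ["hydrogen-bond"]
        assert contacts[0].distance == pytest.approx(3.4)

    def test_carbon_pair_at_4_2_is_not_hydrophobic(self):
        lig, prot = self._pair(("C1", "C"), ("CD1", "LEU", "C"), 4.2)
        assert find_contacts(lig, prot) == []

    def test_cation_anion_at_5_0_is_a_salt_bridge(self):
        lig, prot = self._pair(("N1", "N"), ("OD1", "ASP", "O"), 5.0)
        contacts = find_contacts(lig, prot)
        assert [c.kind for c in contacts] == ["salt-bridge"]

    def test_cutoff_monotonicity(self):
        lig, prot = self._pair(("C1", "C"), ("CD1", "LEU", "C"), 4.2)
        widened = dict(DEFAULT_CUTOFFS, hydrophobic=4.5)
        assert [c.kind for c in find_contacts(lig, prot, widened)] == ["hydrophobic"]

    def test_empty_lists_rejected(self):
        lig, prot = self._pair(("C1", "C"), ("CD1", "LEU", "C"), 3.0)
        with pytest.raises(ValueError):
            find_contacts([], prot)


class TestPlantedComplexRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_recovered_contacts_equal_planted_ground_truth(self, seed):
        spec = ComplexSpec(n_hbond=2, n_salt=1, n_hydrophobic=2, n_pi=1, seed=seed)
        pdb_text, truth = generate_toy_complex(spec)
        lig, prot = split_complex(pdb_text)
        contacts = find_contacts(lig, prot)
        got = {(c.kind, c.ligand_atom, c.protein_residue) for c in contacts}
        want = {(t.kind, t.ligand_atom, t.protein_residue) for t in truth}
        assert got == want
        for c in contacts:
            assert c.distance <= DEFAULT_CUTOFFS[c.kind]

    def test_zero_planted_contacts_yield_empty_list(self):
        pdb_text, truth = generate_toy_complex(
            ComplexSpec(n_hbond=0, n_salt=0, n_hydrophobic=0, n_pi=0, seed=1)
        )
        lig, prot = split_complex(pdb_text)
        assert truth == [] and find_contacts(lig, prot) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_all_pairs_oracle(self, seed):
        pdb_text, _ = generate_toy_complex(ComplexSpec(seed=seed))
        lig, prot = split_complex(pdb_text)
        got = {(c.kind, c.ligand_atom, c.protein_residue) for c in find_contacts(lig, prot)}
        assert got == brute_force_contacts(lig, prot)


class TestSummarizeContacts:
    def test_grouping_takes_min_distance(self):
        lig, prot = split_complex("\n".join([
            pdb_atom("ATOM", 1, "N", "GLY", "A", 1, 3.2, 0, 0, element="N"),
            pdb_atom("ATOM", 2, "O", "GLY", "A", 1, 0, 3.4, 0, element="O"),
            pdb_atom("HETATM", 3, "O1", "LIG", "B", 9, 0, 0, 0, element="O"),
        ]))
        table = summarize_contacts(find_contacts(lig, prot))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["kind"] == "hydrogen-bond"
        assert row["n_contacts"] == 2
        assert row["min_distance"] == pytest.approx(3.2)

    def test_empty_contact_list_gives_empty_table(self):
        assert len(summarize_contacts([])) == 0
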