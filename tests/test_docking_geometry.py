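import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gradescreen.docking_geometry import (
    LigandCoordinates,
    ScreeningCriteria,
    StructureMetadata,
    compute_box,
    compute_rmsd,
    extract_ligand,
    read_pdb,
    redock_check,
    screen_structure,
)


def pdb_atom(kind, serial, name, resname, chain, resnum, x, y, z, occ=1.0, altloc=" ", element=None):
    el = element if element is not None else name[0]
    return (
        f"{kind:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {el:>2}"
    )


def lig(*coords):
    return LigandCoordinates(tuple(coords), "LIG")


class TestReadPdb:
    def test_single_hetatm_fields_read_back(self):
        text = "\n".join([
            "HEADER    TOY                                     01-JAN-20   1ABC",
            pdb_atom("HETATM", 1, "C1", "LIG", "A", 1, 1.5, -2.25, 3.0),
        ])
        atoms, meta = read_pdb(text)
        assert len(atoms) == 1
        assert atoms[0].coords == (1.5, -2.25, 3.0)
        assert atoms[0].element == "C"
        assert meta.pdb_id == "1ABC"

    def test_altloc_duplicates_resolve_to_highest_occupancy(self):
        text = "\n".join([
            pdb_atom("ATOM", 1, "CA", "ALA", "A", 1, 0, 0, 0, occ=0.4, altloc="A"),
            pdb_atom("ATOM", 2, "CA", "ALA", "A", 1, 9, 9, 9, occ=0.6, altloc="B"),
        ])
        atoms, _ = read_pdb(text)
        assert len(atoms) == 1
        assert atoms[0].coords == (9.0, 9.0, 9.0)

    def test_missing_resolution_marked_unknown(self):
        atoms, meta = read_pdb(pdb_atom("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0))
        assert meta.resolution is None

    def test_header_metadata_parsed(self):
        text = "\n".join([
            "EXPDTA    X-RAY DIFFRACTION",
            "REMARK   2 RESOLUTION.    2.10 ANGSTROMS.",
            "SOURCE   2 ORGANISM_SCIENTIFIC: HOMO SAPIENS;",
            pdb_atom("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0),
        ])
        _, meta = read_pdb(text)
        assert meta.resolution == pytest.approx(2.10)
        assert meta.experimental_method == "X-RAY DIFFRACTION"
        assert meta.organism == "HOMO SAPIENS"
        assert meta.chain_count == 1

    def test_no_atoms_is_an_error(self):
        with pytest.raises(ValueError):
            read_pdb("HEADER    EMPTY\nEND\n")


class TestExtractLigand:
    def _complex_text(self):
        return "\n".join([
            pdb_atom("ATOM", 1, "CA", "GLY", "A", 1, 0, 0, 0),
            pdb_atom("HETATM", 2, "C1", "LIG", "A", 90, 1, 0, 0),
            pdb_atom("HETATM", 3, "C2", "LIG", "A", 90, 2, 0, 0),
            pdb_atom("HETATM", 4, "O1", "LIG", "A", 90, 3, 0, 0),
            pdb_atom("HETATM", 5, "N1", "LIG", "A", 90, 4, 0, 0),
            pdb_atom("HETATM", 6, "O", "HOH", "A", 101, 8, 0, 0),
            pdb_atom("HETATM", 7, "O", "HOH", "A", 102, 9, 0, 0),
            pdb_atom("HETATM", 8, "O", "HOH", "A", 103, 10, 0, 0),
            pdb_atom("HETATM", 9, "C1", "LIG", "B", 90, 5, 0, 0),
        ])

    def test_ligand_atoms_in_file_order_waters_excluded(self):
        atoms, _ = read_pdb(self._complex_text())
        ligand = extract_ligand(atoms, "LIG")
        assert len(ligand) == 4
        assert [c[0] for c in ligand.coords] == [1.0, 2.0, 3.0, 4.0]

    def test_first_chain_instance_only(self):
        atoms, _ = read_pdb(self._complex_text())
        ligand = extract_ligand(atoms, "LIG")
        assert (5.0, 0.0, 0.0) not in ligand.coords  # chain B copy ignored

    def test_water_request_and_absent_residue_are_errors(self):
        atoms, _ = read_pdb(self._complex_text())
        with pytest.raises(ValueError, match="solvent"):
            extract_ligand(atoms, "HOH")
        with pytest.raises(ValueError, match="XYZ"):
            extract_ligand(atoms, "XYZ")


class TestScreenStructure:
    def _meta(self, **kw):
        base = dict(
            pdb_id="1ABC", experimental_method="X-RAY DIFFRACTION",
            resolution=2.1, chain_count=1, ligand_mw=434.5, organism="Homo sapiens",
        )
        base.update(kw)
        return StructureMetadata(**base)

    def test_all_criteria_pass(self):
        ok, reasons = screen_structure(self._meta())
        assert ok and reasons == []

    def test_resolution_boundary_is_strict(self):
        ok, reasons = screen_structure(self._meta(resolution=3.0))
        assert not ok and any("resolution" in r for r in reasons)
        assert screen_structure(self._meta(resolution=2.999))[0]

    def test_ligand_mw_boundary_is_inclusive(self):
        assert screen_structure(self._meta(ligand_mw=100.0))[0]
        ok, reasons = screen_structure(self._meta(ligand_mw=95.0))
        assert not ok and any("MW" in r for r in reasons)

    def test_unknown_fields_fail_closed(self):
        ok, reasons = screen_structure(self._meta(resolution=None, organism=None))
        assert not ok
        assert "unknown-field:resolution" in reasons
        assert "unknown-field:organism" in reasons

    def test_multi_chain_rejected_with_every_reason_listed(self):
        ok, reasons = screen_structure(self._meta(chain_count=2, ligand_mw=50))
        assert not ok and len(reasons) == 2


class TestComputeBox:
    def test_single_atom_degenerate_extent(self):
        box = compute_box(lig((0.0, 0.0, 0.0)), padding=4.0)
        assert box.center == (0.0, 0.0, 0.0)
        assert box.size == (8.0, 8.0, 8.0)

    def test_two_atom_hand_case(self):
        box = compute_box(lig((0.0, 0.0, 0.0), (2.0, 4.0, 6.0)), padding=4.0)
        assert box.center == (1.0, 2.0, 3.0)
        assert box.size == (10.0, 12.0, 14.0)

    def test_zero_padding_pure_extent(self):
        box = compute_box(lig((-1.0, -1.0, -1.0), (1.0, 1.0, 1.0)), padding=0.0)
        assert box.center == (0.0, 0.0, 0.0)
        assert box.size == (2.0, 2.0, 2.0)

    def test_matches_brute_force_min_max_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pts = rng.uniform(-30, 30, size=(rng.integers(1, 40), 3))
            box = compute_box(lig(*map(tuple, pts)), padding=4.0)
            for ax in range(3):
                lo, hi = min(p[ax] for p in pts), max(p[ax] for p in pts)
                assert box.center[ax] == (lo + hi) / 2
                assert box.size[ax] == (hi - lo) + 8.0

    def test_containment_with_padding_margin(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-10, 10, size=(25, 3))
        box = compute_box(lig(*map(tuple, pts)), padding=4.0)
        for p in pts:
            for ax in range(3):
                assert abs(p[ax] - box.center[ax]) <= box.size[ax] / 2 - 4.0 + 1e-9

    @given(st.tuples(*[st.floats(-50, 50)] * 3))
    def test_translation_equivariance(self, t):
        pts = [(0.0, 1.0, 2.0), (3.0, -1.0, 5.0), (-2.0, 4.0, 0.0)]
        moved = [(x + t[0], y + t[1], z + t[2]) for x, y, z in pts]
        b0, b1 = compute_box(lig(*pts)), compute_box(lig(*moved))
        assert b1.size == pytest.approx(b0.size)
        assert b1.center == pytest.approx(tuple(c + d for c, d in zip(b0.center, t)))

    def test_empty_coordinates_rejected(self):
        with pytest.raises(ValueError):
            compute_box(LigandCoordinates((), "LIG"))


class TestRmsd:
    def test_identity_is_zero(self):
        a = lig((1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        assert compute_rmsd(a, a) == 0.0

    def test_uniform_translation_is_displacement_magnitude(self):
        a = lig((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (2.0, -1.0, 0.5))
        b = lig(*[(x + 3, y + 4, z) for x, y, z in a.coords])
        assert compute_rmsd(a, b) == pytest.approx(5.0)

    def test_two_atom_hand_case(self):
        a = lig((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        b = lig((0.0, 0.0, 0.0), (3.0, 0.0, 0.0))
        assert compute_rmsd(a, b) == pytest.approx(math.sqrt(2))

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        a = lig(*map(tuple, rng.normal(size=(6, 3))))
        b = lig(*map(tuple, rng.normal(size=(6, 3))))
        assert compute_rmsd(a, b) == pytest.approx(compute_rmsd(b, a))
        shift = (2.0, -3.0, 1.0)
        a2 = lig(*[(x + 2, y - 3, z + 1) for x, y, z in a.coords])
        b2 = lig(*[(x + 2, y - 3, z + 1) for x, y, z in b.coords])
        assert compute_rmsd(a2, b2) == pytest.approx(compute_rmsd(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_rmsd(lig((0.0, 0.0, 0.0)), lig((0.0, 0.0, 0.0), (1.0, 1.0, 1.0)))


class TestRedockCheck:
    @pytest.mark.parametrize("rmsd,expected", [(0.0, True), (2.0, True), (2.01, False)])
    def test_threshold_inclusive_at_two_angstrom(self, rmsd, expected):
        assert redock_check(rmsd) is expected

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            redock_check(-0.1)
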