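"""Steric-clash scanning: parsing, classification, oracle equality."""

import math

import numpy as np
import pytest

from gjvolt.clash import (
    VDW_RADII,
    clash_scan,
    interface_profile,
    parse_selection,
    read_structure,
)

from conftest import pdb_atom_line, write_pdb


class TestReadStructure:
    def test_minimal_two_atom_file(self, toy_pdb):
        path = toy_pdb(
            [
                (1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0, "C"),
                (2, "N", "GLY", "B", 5, -1.5, 0.0, 4.25, "N"),
            ]
        )
        atoms = read_structure(path)
        assert len(atoms) == 2
        assert atoms[0].xyz == (1.0, 2.0, 3.0)
        assert atoms[1].chain == "B" and atoms[1].resnum == 5
        assert atoms[1].element == "N"

    def test_altloc_keeps_highest_occupancy(self, toy_pdb):
        path = toy_pdb(
            [
                (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C", 0.3, "A"),
                (2, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, "C", 0.7, "B"),
            ]
        )
        atoms = read_structure(path)
        assert len(atoms) == 1
        assert atoms[0].xyz[0] == 9.0

    def test_waters_skipped(self, toy_pdb):
        path = toy_pdb(
            [
                (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
                (2, "O", "HOH", "A", 99, 1.0, 1.0, 1.0, "O"),
            ]
        )
        assert len(read_structure(path)) == 1

    def test_truncated_line_names_line(self, tmp_path):
        p = tmp_path / "trunc.pdb"
        p.write_text(
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C") + "\n"
            "ATOM      2  CA  GLY A   2      1.000\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_structure(str(p))

    def test_no_atom_records_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure(str(p))

    def test_unknown_element_warns_default_radius(self, toy_pdb):
        path = toy_pdb(
            [
                (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
                (2, "SE", "MSE", "A", 2, 3.0, 0.0, 0.0, "SE"),
            ]
        )
        with pytest.warns(RuntimeWarning, match="unknown element"):
            atoms = read_structure(path)
        assert atoms[1].vdw == 1.70


class TestParseSelection:
    def test_range_and_single(self):
        assert parse_selection("A:4-6,B:10") == {
            ("A", 4), ("A", 5), ("A", 6), ("B", 10),
        }

    def test_bad_token_rejected(self):
        with pytest.raises(ValueError):
            parse_selection("A4-6")


class TestClashScan:
    def test_carbon_pair_arithmetic(self, toy_pdb):
        # two carbons: radii sum 3.4; at 2.5 A -> clash, at 3.5 A -> contact
        path = toy_pdb(
            [
                (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
                (2, "CA", "GLY", "A", 10, 2.5, 0.0, 0.0, "C"),
                (3, "CA", "VAL", "A", 20, 0.0, 3.5, 0.0, "C"),
            ]
        )
        atoms = read_structure(path)
        rep = clash_scan(atoms, {("A", 1)}, {("A", 10), ("A", 20)}, tolerance=0.4)
        by_res = {r.atom_b.resnum: r for r in rep}
        assert by_res[10].classification == "clash"
        assert by_res[10].overlap == pytest.approx(3.4 - 2.5 - 0.4)
        assert by_res[20].classification == "contact"

    def test_single_residue_self_scan_empty(self, toy_pdb):
        # N-CA-C backbone: every pair is within two covalent bonds
        path = toy_pdb(
            [
                (1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
                (2, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0, "C"),
                (3, "C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"),
            ]
        )
        atoms = read_structure(path)
        assert clash_scan(atoms, {("A", 1)}, {("A", 1)}) == []

    def test_empty_selection_is_error(self, toy_pdb):
        path = toy_pdb([(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C")])
        atoms = read_structure(path)
        with pytest.raises(ValueError, match="non-empty"):
            clash_scan(atoms, set(), {("A", 1)})

    def test_symmetric_in_selection_swap(self, random_structure):
        atoms, sel_a, sel_b = random_structure(200, seed=1)
        r1 = clash_scan(atoms, sel_a, sel_b)
        r2 = clash_scan(atoms, sel_b, sel_a)
        key = lambda r: (id(r.atom_a), id(r.atom_b))
        assert sorted(map(key, r1)) == sorted(map(key, r2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, random_structure, seed):
        atoms, sel_a, sel_b = random_structure(300, seed=seed)
        fast = {
            (id(r.atom_a), id(r.atom_b)): (round(r.distance, 9), r.classification)
            for r in clash_scan(atoms, sel_a, sel_b)
        }
        assert fast == brute_force_scan(atoms, sel_a, sel_b)

    def test_tolerance_monotonicity(self, random_structure):
        atoms, sel_a, sel_b = random_structure(250, seed=3)
        counts = []
        for tol in (0.0, 0.2, 0.4, 0.8, 1.5):
            rep = clash_scan(atoms, sel_a, sel_b, tolerance=tol)
            counts.append(sum(r.classification == "clash" for r in rep))
        assert counts == sorted(counts, reverse=True)


def brute_force_scan(atoms, sel_a, sel_b, tolerance=0.4, cutoff=5.0):
    """O(n^2) all-pairs oracle with independent bond detection."""
    cov = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "H": 0.31}
    n = len(atoms)
    bonded = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(atoms[i].xyz, atoms[j].xyz)
            if d <= cov.get(atoms[i].element, 0.77) + cov.get(
                atoms[j].element, 0.77
            ) + 0.4:
                bonded[i].add(j)
                bonded[j].add(i)
    out = {}
    for i in range(n):
        if (atoms[i].chain, atoms[i].resnum) not in sel_a:
            continue
        for j in range(n):
            if j == i or (atoms[j].chain, atoms[j].resnum) not in sel_b:
                continue
            lo, hi = min(i, j), max(i, j)
            if (id(atoms[lo]), id(atoms[hi])) in out:
                continue
            if atoms[i].element == "H" or atoms[j].element == "H":
                continue
            d = math.dist(atoms[i].xyz, atoms[j].xyz)
            if d > cutoff:
                continue
            two_bond = j in bonded[i] or any(
                j in bonded[k] for k in bonded[i]
            )
            if two_bond:
                continue
            rs = atoms[i].vdw + atoms[j].vdw
            if d < rs - tolerance:
                cls = "clash"
            elif d < rs + 0.5:
                cls = "contact"
            else:
                cls = "none"
            out[(id(atoms[lo]), id(atoms[hi]))] = (round(d, 9), cls)
    return out


@pytest.fixture
def random_structure(toy_pdb):
    """Random atoms in a 18 A box split into two residue selections."""

    def build(n_atoms, seed=0):
        rng = np.random.default_rng(seed)
        elements = rng.choice(["C", "N", "O", "S"], size=n_atoms)
        coords = rng.uniform(0, 18.0, size=(n_atoms, 3))
        lines = []
        for i in range(n_atoms):
            resnum = i // 4 + 1
            lines.append(
                (i + 1, f"X{i % 4}", "UNK", "A", resnum,
                 *np.round(coords[i], 3), elements[i])
            )
        path = toy_pdb(lines, filename=f"rand{seed}.pdb")
        atoms = read_structure(path)
        residues = sorted({(a.chain, a.resnum) for a in atoms})
        half = len(residues) // 2
        return atoms, set(residues[:half]), set(residues[half:])

    return build


class TestInterfaceProfile:
    def _helix_pair(self, toy_pdb, shift=(0.0, 0.0, 0.0)):
        """Two mini 'helices': NT residues 13-15 and TM2 residues 88-90,
        with residue 14 <-> 89 closest at 3.6 A."""
        sx, sy, sz = shift
        lines = [
            (1, "CA", "ALA", "A", 13, 0.0 + sx, 0.0 + sy, 0.0 + sz, "C"),
            (2, "CB", "ALA", "A", 14, 0.0 + sx, 0.0 + sy, 5.0 + sz, "C"),
            (3, "CA", "GLN", "A", 15, 0.0 + sx, 0.0 + sy, 10.0 + sz, "C"),
            (4, "CG", "LEU", "A", 88, 8.0 + sx, 0.0 + sy, 0.0 + sz, "C"),
            (5, "CD1", "THR", "A", 89, 3.6 + sx, 0.0 + sy, 5.0 + sz, "C"),
            (6, "CA", "LEU", "A", 90, 8.0 + sx, 0.0 + sy, 10.0 + sz, "C"),
        ]
        return toy_pdb(lines, filename="helix.pdb")

    def test_constructed_contact_detected(self, toy_pdb):
        atoms = read_structure(self._helix_pair(toy_pdb))
        table = interface_profile(atoms, nt_range=(13, 15), tm2_range=(88, 90))
        row = table[(table.nt_res == 14) & (table.tm2_res == 89)].iloc[0]
        assert row.min_distance == pytest.approx(3.6)
        assert row.classification == "contact"

    def test_unmodeled_residues_flagged_missing(self, toy_pdb):
        atoms = read_structure(self._helix_pair(toy_pdb))
        table = interface_profile(atoms, nt_range=(4, 15), tm2_range=(88, 90))
        missing = table[table.nt_res < 13]
        assert len(missing) > 0
        assert (missing.classification == "missing").all()

    def test_rigid_translation_invariance(self, toy_pdb):
        t1 = interface_profile(
            read_structure(self._helix_pair(toy_pdb)),
            nt_range=(13, 15), tm2_range=(88, 90),
        )
        atoms2 = read_structure(
            self._helix_pair(toy_pdb, shift=(10.0, 10.0, 10.0))
        )
        t2 = interface_profile(atoms2, nt_range=(13, 15), tm2_range=(88, 90))
        assert np.allclose(
            t1.min_distance.fillna(-1), t2.min_distance.fillna(-1), atol=1e-9
        )
        assert (t1.classification == t2.classification).all()

    def test_inter_subunit_pairing_by_chain_adjacency(self, toy_pdb):
        lines = [
            (1, "CB", "ALA", "A", 14, 0.0, 0.0, 0.0, "C"),
            (2, "CD1", "THR", "A", 89, 30.0, 0.0, 0.0, "C"),
            (3, "CB", "ALA", "B", 14, 40.0, 0.0, 0.0, "C"),
            (4, "CD1", "THR", "B", 89, 3.5, 0.0, 0.0, "C"),  # near A:14
        ]
        atoms = read_structure(toy_pdb(lines, filename="inter.pdb"))
        table = interface_profile(
            atoms, nt_range=(14, 14), tm2_range=(89, 89), include_inter=True
        )
        inter = table[(table.nt_chain == "A") & (table.tm2_chain == "B")]
        assert len(inter) == 1
        assert inter.iloc[0].min_distance == pytest.approx(3.5)
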