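"""Structure parsing, interface detection, chain mapping and projection."""

import numpy as np
import pytest

from ptmhotspots import (
    SequenceRecord,
    ValidationError,
    build_residue_map,
    detect_interface,
    map_structure_to_alignment,
    project_scores,
    read_structure,
)
from ptmhotspots.features import FeatureVector
from ptmhotspots.map_builder import MAP
from ptmhotspots.scoring import ScoredMAP
from ptmhotspots.structure import Atom, Residue, StructureChain
from ptmhotspots.synthetic import write_structure_pair

from conftest import phospho


def _chain(chain_id, residues):
    """residues: list of (number, name, [(atom, x, y, z), ...])."""
    return StructureChain(
        chain_id,
        [
            Residue(num, name, [Atom(*a) for a in atoms])
            for num, name, atoms in residues
        ],
    )


def _single_atom_chain(chain_id, coords, start=1):
    return _chain(
        chain_id,
        [
            (start + i, "ALA", [("CA", x, y, z)])
            for i, (x, y, z) in enumerate(coords)
        ],
    )


class TestReadStructure:
    def test_two_residue_chain(self, tmp_path):
        path = tmp_path / "s.pdb"
        write_structure_pair(
            _single_atom_chain("A", [(0, 0, 0), (3.8, 0, 0)]),
            _single_atom_chain("B", [(0, 50, 0)]),
            path,
        )
        chain = read_structure(path, "A")
        assert [r.number for r in chain.residues] == [1, 2]

    def test_hetatm_and_water_skipped(self, tmp_path):
        path = tmp_path / "h.pdb"
        path.write_text(
            "HETATM    1  C1  LIG A   1      0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A   2      1.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValidationError, match="no polymer residues"):
            read_structure(path, "A")

    def test_absent_chain(self, tmp_path):
        path = tmp_path / "s.pdb"
        write_structure_pair(
            _single_atom_chain("A", [(0, 0, 0)]),
            _single_atom_chain("B", [(0, 50, 0)]),
            path,
        )
        with pytest.raises(ValidationError, match="'C'"):
            read_structure(path, "C")

    def test_hydrogens_skipped(self, tmp_path):
        path = tmp_path / "s.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1      0.500   0.000   0.000  1.00  0.00           H\n"
            "END\n"
        )
        chain = read_structure(path, "A")
        assert [a.name for a in chain.residues[0].atoms] == ["CA"]


class TestDetectInterface:
    def test_inclusive_boundary(self):
        a = _single_atom_chain("A", [(0, 0, 0)])
        b = _single_atom_chain("B", [(3.99, 0, 0)])
        ia, ib = detect_interface(a, b, 4.0)
        assert ia.residue_positions == {1} and ib.residue_positions == {1}

    def test_just_outside(self):
        a = _single_atom_chain("A", [(0, 0, 0)])
        b = _single_atom_chain("B", [(4.01, 0, 0)])
        ia, ib = detect_interface(a, b, 4.0)
        assert not ia.residue_positions and not ib.residue_positions

    def test_invalid_cutoff(self):
        a = _single_atom_chain("A", [(0, 0, 0)])
        with pytest.raises(ValidationError):
            detect_interface(a, a, 0.0)

    @staticmethod
    def _random_chain(rng, chain_id, n=50):
        coords = []
        residues = []
        for i in range(n):
            center = rng.uniform(0, 40, 3)
            atoms = [
                ("C" + str(k), *(center + rng.uniform(-1, 1, 3)))
                for k in range(rng.integers(1, 4))
            ]
            residues.append((i + 1, "GLY", atoms))
        return _chain(chain_id, residues)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = self._random_chain(rng, "A")
            b = self._random_chain(rng, "B")
            ia, ib = detect_interface(a, b, 4.0)
            brute_a, brute_b = set(), set()
            for ra in a.residues:
                for rb in b.residues:
                    for aa in ra.atoms:
                        for ab in rb.atoms:
                            if np.linalg.norm(aa.coord - ab.coord) <= 4.0:
                                brute_a.add(ra.number)
                                brute_b.add(rb.number)
            assert ia.residue_positions == brute_a
            assert ib.residue_positions == brute_b

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        a = self._random_chain(rng, "A", 20)
        b = self._random_chain(rng, "B", 20)
        ia, ib = detect_interface(a, b, 4.0)
        jb, ja = detect_interface(b, a, 4.0)
        assert ia.residue_positions == ja.residue_positions
        assert ib.residue_positions == jb.residue_positions

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(10)
        a = self._random_chain(rng, "A", 20)
        b = self._random_chain(rng, "B", 20)
        prev_a = set()
        for cutoff in (2.0, 4.0, 6.0, 8.0):
            ia, _ = detect_interface(a, b, cutoff)
            assert prev_a <= ia.residue_positions
            prev_a = ia.residue_positions

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        a = self._random_chain(rng, "A", 15)
        b = self._random_chain(rng, "B", 15)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([5.0, -3.0, 11.0])

        def moved(chain):
            return StructureChain(
                chain.chain_id,
                [
                    Residue(
                        r.number,
                        r.name,
                        [Atom(at.name, *(R @ at.coord + t)) for at in r.atoms],
                    )
                    for r in chain.residues
                ],
            )

        ia, ib = detect_interface(a, b, 4.0)
        ja, jb = detect_interface(moved(a), moved(b), 4.0)
        assert ia.residue_positions == ja.residue_positions
        assert ib.residue_positions == jb.residue_positions


class TestChainMapping:
    def test_exact_substring_offsets(self, rgs_demo):
        """The fixture chain covers AtRGS1 284-416, so residue numbers map
        to columns with offset 283 plus the member's gap pattern."""
        from ptmhotspots import read_alignment

        aln = read_alignment(rgs_demo["plant_alignment"])
        member = aln.row("AtRGS1")
        rmap = build_residue_map(member)
        chain = read_structure(rgs_demo["structure"], "A")
        mapping = map_structure_to_alignment(chain, member, rmap)
        # AtRGS1 has no gaps before column 460, so columns equal natives
        assert mapping[284] == 284
        assert mapping[365] == 365
        assert mapping[416] == 416

    def test_single_substitution_tolerated(self):
        member = SequenceRecord("M", "ACDEFGHIKLMNPQRSTVWY" * 5)
        rmap = build_residue_map(member)
        seq = list(member.ungapped)
        seq[10] = "W"  # one substitution in 100 residues
        chain = _chain(
            "A",
            [
                (i + 1, _three(ch), [("CA", float(i), 0.0, 0.0)])
                for i, ch in enumerate(seq)
            ],
        )
        mapping = map_structure_to_alignment(chain, member, rmap)
        assert mapping[1] == 1 and mapping[100] == 100

    def test_low_identity_rejected_with_value(self):
        member = SequenceRecord("M", "ACDEFGHIKLMNPQRSTVWY" * 3)
        rmap = build_residue_map(member)
        rng = np.random.default_rng(5)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        chain = _chain(
            "A",
            [
                (i + 1, _three(letters[k]), [("CA", float(i), 0.0, 0.0)])
                for i, k in enumerate(rng.integers(0, 20, 60))
            ],
        )
        with pytest.raises(ValidationError, match="identity"):
            map_structure_to_alignment(chain, member, rmap)


def _three(letter):
    from ptmhotspots.synthetic import _AA3

    return _AA3[letter]


class TestProjection:
    def test_bins_round_trip_through_bfactors(self, tmp_path, rgs_demo):
        chain = read_structure(rgs_demo["structure"], "A")
        mapping = {r.number: r.number for r in chain.residues}  # identity cols
        scored = []
        for col, b in [(339, 4), (365, 2), (405, 1)]:
            m = MAP(col, [phospho("AtRGS1", col)])
            s = ScoredMAP(map=m, IS=float(b), rank=1, bin=b)
            scored.append(s)
        out = tmp_path / "proj.pdb"
        project_scores(rgs_demo["structure"], "A", mapping, scored, out)
        back = read_structure(out, "A")
        # re-parse B-factors directly from the text
        bf = {}
        for line in out.read_text().splitlines():
            if line.startswith("ATOM") and line[21] == "A":
                bf[int(line[22:26])] = line[60:66].strip()
        assert bf[339] == "4.00"
        assert bf[365] == "2.00"
        assert bf[405] == "1.00"
        assert bf[300] == "0.00"  # unscored residue
        assert len(back.residues) == len(chain.residues)
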