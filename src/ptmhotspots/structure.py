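"""Structure handling: PDB-format chains, interface detection at a
distance cutoff, chain-to-alignment mapping, and projection of MAP score
bins onto coordinates via the B-factor column.

Only heavy atoms are considered (crystal structures usually lack
hydrogens); the contact cutoff is inclusive (<=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.SeqUtils import seq1

from .io import SequenceRecord, ValidationError
from .map_builder import ResidueMap
from .scoring import ScoredMAP


@dataclass
class Atom:
    name: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: list[Atom]


@dataclass
class StructureChain:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"chain {self.chain_id!r} has no residues")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValidationError(
                f"chain {self.chain_id!r}: residue numbers not strictly increasing"
            )
        for r in self.residues:
            if not r.atoms:
                raise ValidationError(
                    f"chain {self.chain_id!r} residue {r.number}: no atoms"
                )

    @property
    def sequence(self) -> str:
        """One-letter translation of the residue names (unknown -> X)."""
        return "".join(seq1(r.name, undef_code="X") for r in self.residues)

    def heavy_atom_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_atoms x 3 coordinates, n_atoms residue indices)."""
        coords, owners = [], []
        for i, res in enumerate(self.residues):
            for atom in res.atoms:
                coords.append((atom.x, atom.y, atom.z))
                owners.append(i)
        return np.asarray(coords, float), np.asarray(owners, int)


@dataclass
class InterfaceSet:
    """Native residue positions of one family member at an interface."""

    protein_id: str
    residue_positions: set[int] = field(default_factory=set)


def _is_hydrogen(atom) -> bool:
    elem = (atom.element or "").strip().upper()
    if elem:
        return elem in ("H", "D")
    return atom.get_name().strip().upper().startswith("H")


def read_structure(path: str | Path, chain_id: str) -> StructureChain:
    """Read ATOM records of one chain from PDB-format text.

    HETATM records, waters and hydrogens are skipped. Raises when the chain
    is absent, contains no residues after filtering, or a coordinate field
    fails to parse.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except PDBConstructionException as exc:
        raise ValidationError(f"{path}: unparseable PDB record ({exc})") from exc
    model = next(iter(structure))
    if chain_id not in [c.id for c in model]:
        raise ValidationError(
            f"{path}: chain {chain_id!r} not present "
            f"(found {[c.id for c in model]})"
        )
    residues = []
    for res in model[chain_id]:
        hetfield = res.id[0]
        if hetfield != " ":  # HETATM / water
            continue
        atoms = [
            Atom(a.get_name(), *map(float, a.coord))
            for a in res
            if not _is_hydrogen(a)
        ]
        if atoms:
            residues.append(Residue(res.id[1], res.get_resname(), atoms))
    if not residues:
        raise ValidationError(
            f"{path}: chain {chain_id!r} has no polymer residues"
        )
    return StructureChain(chain_id, residues)


def detect_interface(
    a: StructureChain, b: StructureChain, cutoff: float = 4.0
) -> tuple[InterfaceSet, InterfaceSet]:
    """Residues of each chain with any heavy atom within *cutoff* (<=) of a
    heavy atom of the other chain. Exact all-pairs semantics (implemented
    with a k-d tree)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    coords_a, owners_a = a.heavy_atom_array()
    coords_b, owners_b = b.heavy_atom_array()
    tree_b = cKDTree(coords_b)
    pairs = tree_b.query_ball_point(coords_a, r=cutoff)
    res_a: set[int] = set()
    res_b: set[int] = set()
    for ia, hits in enumerate(pairs):
        if hits:
            res_a.add(a.residues[owners_a[ia]].number)
            for ib in hits:
                res_b.add(b.residues[owners_b[ib]].number)
    return (
        InterfaceSet(a.chain_id, res_a),
        InterfaceSet(b.chain_id, res_b),
    )


def map_structure_to_alignment(
    chain: StructureChain,
    member: SequenceRecord,
    rmap: ResidueMap,
    min_identity: float = 0.95,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> dict[int, int]:
    """Map structured residue numbers to alignment columns.

    The chain's one-letter sequence is globally aligned to the member's
    ungapped sequence (BLOSUM62, affine gaps); aligned identity must reach
    *min_identity*. Residues outside the aligned region are absent from
    the mapping.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    chain_seq = chain.sequence
    member_seq = member.ungapped
    alignment = aligner.align(chain_seq, member_seq)[0]
    matches = aligned = 0
    pairs: list[tuple[int, int]] = []  # (chain index, member index), 0-based
    for (cs, ce), (ms, me) in zip(*alignment.aligned):
        for k in range(ce - cs):
            ci, mi = cs + k, ms + k
            aligned += 1
            if chain_seq[ci] == member_seq[mi]:
                matches += 1
            pairs.append((ci, mi))
    identity = matches / aligned if aligned else 0.0
    if identity < min_identity:
        raise ValidationError(
            f"chain {chain.chain_id!r} aligns to {member.seq_id!r} with "
            f"identity {identity:.3f} < required {min_identity:.2f}"
        )
    return {
        chain.residues[ci].number: rmap.to_column(mi + 1) for ci, mi in pairs
    }


def project_scores(
    structure_path: str | Path,
    chain_id: str,
    mapping: dict[int, int],
    scored: Sequence[ScoredMAP],
    out_path: str | Path,
) -> None:
    """Write a PDB copy with every atom's B-factor set to its residue's
    score bin (two decimals); residues without a scored MAP get 0.00."""
    bins = {s.column: (s.bin or 0) for s in scored}
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    structure = parser.get_structure("s", str(structure_path))
    for model in structure:
        for chain in model:
            for res in chain:
                value = 0.0
                if chain.id == chain_id and res.id[0] == " ":
                    column = mapping.get(res.id[1])
                    if column is not None:
                        value = float(bins.get(column, 0))
                for atom in res:
                    atom.set_bfactor(value)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
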