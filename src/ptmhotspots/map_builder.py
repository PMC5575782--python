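"""Native-to-alignment coordinate maps, profile-to-profile merging, and
grouping of PTM records into modified alignment positions (MAPs).

The profile merger performs a global affine-gap dynamic program over the
*columns* of the two input profiles: columns of either profile are never
split or reordered, only all-gap columns are inserted. The column-pair
objective is the expected substitution score
``sum_x sum_y f_A(x) f_B(y) S(x, y)`` with residue frequencies taken over
non-gap letters; a column that is all-gap in its profile scores zero
against anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .io import (
    GAP,
    AMINO_ACIDS,
    Alignment,
    PTMRecord,
    SequenceRecord,
    ValidationError,
)


class GapColumnError(LookupError):
    """A gap column was queried for a native position."""


@dataclass
class ResidueMap:
    """Bijection between a row's ungapped positions and its non-gap columns."""

    seq_id: str
    _native_to_col: np.ndarray  # index i-1 -> column (1-based)
    _col_to_native: dict[int, int]

    @classmethod
    def from_row(cls, row: SequenceRecord) -> "ResidueMap":
        cols = [
            j + 1 for j, ch in enumerate(row.gapped_residues) if ch != GAP
        ]
        return cls(
            seq_id=row.seq_id,
            _native_to_col=np.asarray(cols, dtype=np.int64),
            _col_to_native={c: i + 1 for i, c in enumerate(cols)},
        )

    @property
    def ungapped_length(self) -> int:
        return len(self._native_to_col)

    def to_column(self, native_pos: int) -> int:
        if not 1 <= native_pos <= len(self._native_to_col):
            raise ValidationError(
                f"{self.seq_id}: native position {native_pos} outside "
                f"1..{len(self._native_to_col)}"
            )
        return int(self._native_to_col[native_pos - 1])

    def to_native(self, column: int) -> int:
        try:
            return self._col_to_native[column]
        except KeyError:
            raise GapColumnError(
                f"{self.seq_id}: column {column} is a gap (or out of range)"
            ) from None


def build_residue_map(row: SequenceRecord) -> ResidueMap:
    return ResidueMap.from_row(row)


def build_residue_maps(aln: Alignment) -> dict[str, ResidueMap]:
    return {r.seq_id: ResidueMap.from_row(r) for r in aln.rows}


@dataclass
class MAP:
    """A modified alignment position: a column harboring >= 1 observed PTM."""

    column: int
    ptms: list[PTMRecord]
    features: Optional["FeatureVector"] = None  # noqa: F821  (filled later)
    score: Optional[float] = None

    @property
    def known_function(self) -> bool:
        return any(p.known_function for p in self.ptms)


def build_maps(
    ptms: Iterable[PTMRecord], rmaps: dict[str, ResidueMap]
) -> list[MAP]:
    """Group PTM records by the alignment column their residue occupies."""
    by_column: dict[int, list[PTMRecord]] = {}
    for rec in ptms:
        if rec.protein_id not in rmaps:
            raise ValidationError(
                f"PTM on {rec.protein_id!r} has no residue map"
            )
        col = rmaps[rec.protein_id].to_column(rec.native_pos)
        by_column.setdefault(col, []).append(rec)
    return [
        MAP(column=col, ptms=sorted(recs, key=lambda r: r.key))
        for col, recs in sorted(by_column.items())
    ]


# ---------------------------------------------------------------------------
# profile-to-profile alignment

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def load_matrix(name_or_path: str = "BLOSUM62") -> np.ndarray:
    """A 20x20 substitution matrix over the standard amino-acid order.

    *name_or_path* is either a named matrix shipped with Biopython (e.g.
    ``BLOSUM62``) or a path to an NCBI-format matrix text file.
    """
    try:
        mat = substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        mat = substitution_matrices.read(name_or_path)
    out = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


def column_frequencies(aln: Alignment) -> np.ndarray:
    """Per-column residue frequencies (n_columns x 20) over non-gap letters.

    All-gap columns yield a zero row.
    """
    freq = np.zeros((aln.n_columns, 20))
    for row in aln.rows:
        for j, ch in enumerate(row.gapped_residues):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                freq[j, idx] += 1.0
    totals = freq.sum(axis=1, keepdims=True)
    np.divide(freq, totals, out=freq, where=totals > 0)
    return freq


_MATCH, _GAP_IN_B, _GAP_IN_A = 0, 1, 2  # tie-break preference order


def profile_align(
    a: Alignment,
    b: Alignment,
    matrix: Optional[np.ndarray] = None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> Alignment:
    """Merge two alignments by a global affine-gap profile-profile DP.

    The result contains all rows of *a* followed by all rows of *b*; within
    each profile the relative column order is preserved and no column is
    split. Deleting columns that are all-gap across one profile's rows
    recovers that profile exactly. A gap run of length L costs
    ``gap_open + (L - 1) * gap_extend``. On ties the traceback prefers a
    column match over a gap in *b* over a gap in *a*.
    """
    shared = set(a.ids) & set(b.ids)
    if shared:
        raise ValidationError(f"profiles share seq_id(s): {sorted(shared)}")
    S = load_matrix() if matrix is None else matrix
    fa = column_frequencies(a)
    fb = column_frequencies(b)
    m, n = a.n_columns, b.n_columns
    pair = fa @ S @ fb.T  # m x n column-pair scores; all-gap rows give 0

    NEG = -np.inf
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # ends with column of a vs gap in b
    Y = np.full((m + 1, n + 1), NEG)  # ends with gap in a vs column of b
    # int8 traceback: predecessor state of each cell
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = _MATCH if i == 1 else _GAP_IN_B
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptrY[0, j] = _MATCH if j == 1 else _GAP_IN_A

    def _argmax3(c0, c1, c2):
        # preference M > X > Y on exact ties
        best = np.where(c0 >= c1, c0, c1)
        best = np.where(best >= c2, best, c2)
        choice = np.where(
            (c0 >= c1) & (c0 >= c2),
            _MATCH,
            np.where(c1 >= c2, _GAP_IN_B, _GAP_IN_A),
        ).astype(np.int8)
        return best, choice

    for i in range(1, m + 1):
        # match state: diagonal predecessors from row i-1
        best, choice = _argmax3(M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1])
        M[i, 1:] = pair[i - 1, :] + best
        ptrM[i, 1:] = choice
        # gap-in-b state: vertical predecessors from row i-1, same column
        best, choice = _argmax3(
            M[i - 1, :] + gap_open,
            X[i - 1, :] + gap_extend,
            Y[i - 1, :] + gap_open,
        )
        keep = best > X[i, :]  # preserve the j == 0 initialization
        X[i, keep] = best[keep]
        ptrX[i, keep] = choice[keep]
        # gap-in-a state: horizontal, sequential in j
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, n + 1):
            c0 = Mi[j - 1] + gap_open
            c1 = Xi[j - 1] + gap_open
            c2 = Yi[j - 1] + gap_extend
            if c0 >= c1 and c0 >= c2:
                Yi[j], ptrY[i, j] = c0, _MATCH
            elif c1 >= c2:
                Yi[j], ptrY[i, j] = c1, _GAP_IN_B
            else:
                Yi[j], ptrY[i, j] = c2, _GAP_IN_A

    finals = (M[m, n], X[m, n], Y[m, n])
    state = int(np.argmax([finals[_MATCH], finals[_GAP_IN_B], finals[_GAP_IN_A]]))
    # argmax returns the first maximum, which matches the M > X > Y preference

    ops: list[int] = []
    i, j = m, n
    while i > 0 or j > 0:
        ops.append(state)
        if state == _MATCH:
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == _GAP_IN_B:
            state = int(ptrX[i, j])
            i -= 1
        else:
            state = int(ptrY[i, j])
            j -= 1
    ops.reverse()

    a_chars = [[] for _ in a.rows]
    b_chars = [[] for _ in b.rows]
    ia = ib = 0
    for op in ops:
        if op == _MATCH:
            for k, row in enumerate(a.rows):
                a_chars[k].append(row.gapped_residues[ia])
            for k, row in enumerate(b.rows):
                b_chars[k].append(row.gapped_residues[ib])
            ia += 1
            ib += 1
        elif op == _GAP_IN_B:
            for k, row in enumerate(a.rows):
                a_chars[k].append(row.gapped_residues[ia])
            for k in range(len(b.rows)):
                b_chars[k].append(GAP)
            ia += 1
        else:
            for k in range(len(a.rows)):
                a_chars[k].append(GAP)
            for k, row in enumerate(b.rows):
                b_chars[k].append(row.gapped_residues[ib])
            ib += 1

    rows = [
        SequenceRecord(
            seq_id=r.seq_id,
            gapped_residues="".join(chars),
            organism=r.organism,
            is_query=r.is_query,
        )
        for r, chars in zip(list(a.rows) + list(b.rows), a_chars + b_chars)
    ]
    return Alignment(rows)


def profile_alignment_score(
    a: Alignment,
    b: Alignment,
    matrix: Optional[np.ndarray] = None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Score of the optimal merge (exposed for testing against oracles)."""
    merged = profile_align(a, b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    return score_merged(merged, set(a.ids), matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)


def score_merged(
    merged: Alignment,
    a_ids: set[str],
    matrix: Optional[np.ndarray] = None,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Re-score a merged alignment under the declared column-pair objective.

    Independent of the DP: walks the merged columns, classifying each as a
    match or as a gap inserted into one profile, and sums pair scores plus
    affine gap costs.
    """
    S = load_matrix() if matrix is None else matrix
    rows_a = [r for r in merged.rows if r.seq_id in a_ids]
    rows_b = [r for r in merged.rows if r.seq_id not in a_ids]
    sub_a = Alignment([SequenceRecord(r.seq_id, r.gapped_residues) for r in rows_a])
    sub_b = Alignment([SequenceRecord(r.seq_id, r.gapped_residues) for r in rows_b])
    fa = column_frequencies(sub_a)
    fb = column_frequencies(sub_b)
    a_present = np.array(
        [any(r.gapped_residues[j] != GAP for r in rows_a) for j in range(merged.n_columns)]
    )
    b_present = np.array(
        [any(r.gapped_residues[j] != GAP for r in rows_b) for j in range(merged.n_columns)]
    )
    total = 0.0
    prev_gap = None  # which profile the previous merged column gapped
    for j in range(merged.n_columns):
        if a_present[j] and b_present[j]:
            total += float(fa[j] @ S @ fb[j])
            prev_gap = None
        else:
            side = "b" if a_present[j] else "a"
            total += gap_extend if prev_gap == side else gap_open
            prev_gap = side
    return total


def extract_profile(merged: Alignment, ids: Iterable[str]) -> Alignment:
    """Restrict *merged* to the named rows and drop their all-gap columns."""
    ids = list(ids)
    rows = [merged.row(i) for i in ids]
    keep = [
        j
        for j in range(merged.n_columns)
        if any(r.gapped_residues[j] != GAP for r in rows)
    ]
    return Alignment(
        [
            SequenceRecord(
                seq_id=r.seq_id,
                gapped_residues="".join(r.gapped_residues[j] for j in keep),
                organism=r.organism,
                is_query=r.is_query,
            )
            for r in rows
        ]
    )
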