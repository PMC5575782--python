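"""Per-MAP feature extraction from a family alignment and its PTM records.

Feature definitions
-------------------
TRC   total residue conservation: frequency of the most common residue in
      the column, over non-gap rows.
PAC   phospho-acceptor conservation: fraction of non-gap rows carrying
      S, T or Y.
membership   fraction of rows that are non-gap at the column.
PC    PTM count: distinct (protein, position, type) modifications at the
      column.
CPC   cluster PTM count: total PTMs within +/- window columns, including
      the target column itself.
NC    neighbor MAP count within the window, excluding the target.
NKC   neighbor known-function count: neighboring MAPs carrying at least
      one modification with published functional evidence.
KF    whether the MAP itself carries a known-functional modification.
PPI   whether the column holds any residue at a protein-protein interface.
PRC   PTM residue conservation: fraction of non-gap rows whose letter
      belongs to the acceptor class of the MAP's dominant modification
      type.

Conservation denominators use non-gap rows only; gap handling is isolated
in ``membership``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .io import GAP, Alignment, PTMRecord, PTMType, ValidationError
from .map_builder import MAP, ResidueMap

PHOSPHO_ACCEPTORS = frozenset("STY")

ACCEPTOR_CLASSES: dict[PTMType, frozenset] = {
    PTMType.phosphorylation: frozenset("STY"),
    PTMType.ubiquitination: frozenset("K"),
    PTMType.acetylation: frozenset("K"),
    PTMType.methylation: frozenset("KR"),
}


@dataclass
class FeatureVector:
    pac: float
    trc: float
    membership: float
    pc: int
    cpc: int
    nc: int
    nkc: int
    kf: bool
    ppi: bool
    prc: float


class ColumnConservation(NamedTuple):
    trc: float
    pac: float
    membership: float
    degenerate: bool  # all-gap column


def _column_letters(aln: Alignment, column: int, scope: str) -> str:
    if scope == "query":
        rows = aln.query_rows()
        if not rows:
            raise ValidationError("scope='query' but no rows are flagged is_query")
    elif scope == "all":
        rows = aln.rows
    else:
        raise ValidationError(f"unknown scope {scope!r} (use 'all' or 'query')")
    if not 1 <= column <= aln.n_columns:
        raise ValidationError(f"column {column} outside 1..{aln.n_columns}")
    return "".join(r.gapped_residues[column - 1] for r in rows)


def column_conservation(
    aln: Alignment, column: int, scope: str = "all"
) -> ColumnConservation:
    """TRC, PAC and membership of one alignment column.

    An all-gap column returns (0, 0, 0) with the degenerate flag set.
    """
    letters = _column_letters(aln, column, scope)
    residues = [ch for ch in letters if ch != GAP]
    if not residues:
        return ColumnConservation(0.0, 0.0, 0.0, True)
    n = len(residues)
    counts: dict[str, int] = {}
    for ch in residues:
        counts[ch] = counts.get(ch, 0) + 1
    trc = max(counts.values()) / n
    pac = sum(1 for ch in residues if ch in PHOSPHO_ACCEPTORS) / n
    membership = n / len(letters)
    return ColumnConservation(trc, pac, membership, False)


def ptm_count(map_: MAP) -> int:
    """Distinct (protein, position, type) modifications in the MAP."""
    return len({p.key for p in map_.ptms})


class ClusterStats(NamedTuple):
    cpc: int
    nc: int
    nkc: int
    neighbor_known: bool


def cluster_window_stats(
    maps: Sequence[MAP], column: int, window: int
) -> ClusterStats:
    """Cluster PTM count and neighbor statistics around one MAP column.

    CPC sums PTM counts over all MAPs within the window *including* the
    target column; NC and NKC run over neighbors only (the target is
    excluded). Windows truncate silently at the alignment bounds.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    if not any(m.column == column for m in maps):
        raise ValidationError(f"column {column} is not a MAP")
    cpc = nc = nkc = 0
    for m in maps:
        d = abs(m.column - column)
        if d > window:
            continue
        cpc += ptm_count(m)
        if d >= 1:
            nc += 1
            if m.known_function:
                nkc += 1
    return ClusterStats(cpc, nc, nkc, nkc >= 1)


def interface_residence(
    map_: MAP,
    interfaces: Iterable["InterfaceSet"],  # noqa: F821
    rmaps: dict[str, ResidueMap],
) -> bool:
    """Whether the MAP column holds any residue of any interface set.

    Interface sets are expressed in native coordinates of named family
    members; membership is tested by translating each interface residue to
    its alignment column.
    """
    for iface in interfaces:
        if iface.protein_id not in rmaps:
            raise ValidationError(
                f"interface set names unknown protein {iface.protein_id!r}"
            )
        rmap = rmaps[iface.protein_id]
        for pos in iface.residue_positions:
            if rmap.to_column(pos) == map_.column:
                return True
    return False


def dominant_ptm_type(map_: MAP) -> PTMType:
    """Most frequent modification type in the MAP; ties go to
    phosphorylation first, then alphabetically."""
    counts: dict[PTMType, int] = {}
    for p in map_.ptms:
        counts[p.ptm_type] = counts.get(p.ptm_type, 0) + 1
    return min(
        counts,
        key=lambda t: (-counts[t], t is not PTMType.phosphorylation, t.value),
    )


def ptm_residue_conservation(
    map_: MAP, aln: Alignment, scope: str = "all"
) -> float:
    """Fraction of non-gap rows whose letter can accept the MAP's dominant
    modification type. For type ``other`` the acceptor class is the set of
    modified letters actually observed in the MAP."""
    dom = dominant_ptm_type(map_)
    acceptors = ACCEPTOR_CLASSES.get(dom)
    if acceptors is None:
        acceptors = frozenset(p.residue for p in map_.ptms if p.ptm_type is dom)
    letters = [
        ch for ch in _column_letters(aln, map_.column, scope) if ch != GAP
    ]
    if not letters:
        return 0.0
    return sum(1 for ch in letters if ch in acceptors) / len(letters)


class CrosstalkPair(NamedTuple):
    phospho: PTMRecord
    ubiquitin: PTMRecord
    distance: int


def crosstalk_pairs(
    ptms: Iterable[PTMRecord], window: int = 5
) -> list[CrosstalkPair]:
    """Same-protein phosphorylation/ubiquitination pairs within *window*
    residues (inclusive), sorted by protein then phospho position."""
    records = list(ptms)
    phos = [p for p in records if p.ptm_type is PTMType.phosphorylation]
    ubiq = [u for u in records if u.ptm_type is PTMType.ubiquitination]
    pairs = [
        CrosstalkPair(p, u, abs(p.native_pos - u.native_pos))
        for p in phos
        for u in ubiq
        if p.protein_id == u.protein_id
        and abs(p.native_pos - u.native_pos) <= window
    ]
    pairs.sort(key=lambda c: (c.phospho.protein_id, c.phospho.native_pos, c.ubiquitin.native_pos))
    return pairs


def compute_features(
    aln: Alignment,
    maps: Sequence[MAP],
    rmaps: dict[str, ResidueMap],
    interfaces: Iterable["InterfaceSet"] = (),  # noqa: F821
    window: int = 2,
    scope: str = "all",
) -> list[MAP]:
    """Fill the FeatureVector of every MAP in place and return the list."""
    interfaces = list(interfaces)
    for m in maps:
        cons = column_conservation(aln, m.column, scope=scope)
        stats = cluster_window_stats(maps, m.column, window)
        m.features = FeatureVector(
            pac=cons.pac,
            trc=cons.trc,
            membership=cons.membership,
            pc=ptm_count(m),
            cpc=stats.cpc,
            nc=stats.nc,
            nkc=stats.nkc,
            kf=m.known_function,
            ppi=interface_residence(m, interfaces, rmaps),
            prc=ptm_residue_conservation(m, aln, scope=scope),
        )
    return list(maps)


def serialize_members(map_: MAP) -> str:
    return ",".join(
        f"{p.protein_id}:{p.native_pos}:{p.ptm_type.value}" for p in map_.ptms
    )


def feature_table(maps: Sequence[MAP]) -> pd.DataFrame:
    """One row per MAP with all feature fields (TSV-ready)."""
    rows = []
    for m in maps:
        if m.features is None:
            raise ValidationError(f"MAP at column {m.column} has no features")
        f = m.features
        rows.append(
            {
                "column": m.column,
                "PAC": round(f.pac, 6),
                "TRC": round(f.trc, 6),
                "membership": round(f.membership, 6),
                "PC": f.pc,
                "CPC": f.cpc,
                "NC": f.nc,
                "NKC": f.nkc,
                "KF": int(f.kf),
                "PPI": int(f.ppi),
                "PRC": round(f.prc, 6),
                "member_ptms": serialize_members(m),
            }
        )
    return pd.DataFrame(rows)
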