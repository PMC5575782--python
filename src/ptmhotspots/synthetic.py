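"""Synthetic families, PTM tables and structure pairs with known ground
truth, so every pipeline stage is testable without external downloads.

Family model
------------
Sequences evolve on a star phylogeny: an ancestor is drawn from the residue
background and each descendant copies the ancestral letter at column j with
probability ``c_j`` (the per-column conservation), otherwise drawing from
the background. Contiguous gap segments are masked into each row at a
per-column start rate. Star sampling is sufficient here because every
feature under test depends only on column composition, not on phylogenetic
covariance.

Hotspot model
-------------
Planted hotspot columns are forced to high phospho-acceptor content and
receive ``max(1, Poisson(lambda))`` phosphorylation records on distinct
sequences. A subset of hotspots is *functional*: their records carry the
known-function flag, one extra coincident known-functional record joins the
column (emulating a plant site precisely coincident with a curated site
from another family member), the column is marked interface-resident, and
two flanking reference MAPs at +/- window columns carry
``max(1, Poisson(lambda / 2))`` known-functional records each — emulating
the dense functional clusters in which curated family PTMs concentrate.
Background columns receive exactly one record and sit more than
``2 * window`` columns from every hotspot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .features import compute_features
from .io import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    PTMRecord,
    PTMType,
    SequenceRecord,
    ValidationError,
)
from .map_builder import build_maps, build_residue_maps
from .scoring import ScoredMAP, Weights, bin_scores, rank_maps, score_maps
from .structure import Atom, InterfaceSet, Residue, StructureChain

_ACCEPTORS = "ST"
_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class SyntheticTruth:
    hotspot_columns: set[int] = field(default_factory=set)
    functional_columns: set[int] = field(default_factory=set)
    background_columns: set[int] = field(default_factory=set)
    reference_columns: set[int] = field(default_factory=set)
    interface_truth: list[tuple[str, int]] = field(default_factory=list)


def simulate_family(
    n_seqs: int,
    length: int,
    conservation_profile: float | Sequence[float] = 0.6,
    gap_rate: float = 0.0,
    seed: int = 0,
    background_freqs: Optional[Sequence[float]] = None,
    mean_gap_length: float = 3.0,
) -> Alignment:
    """Sample a star-phylogeny family alignment.

    *conservation_profile* is a scalar or per-column array of copy
    probabilities in [0, 1]; *gap_rate* is the per-column probability that
    a gap segment (geometric length, mean *mean_gap_length*) starts in a
    given row. Fully reproducible from *seed*.
    """
    if n_seqs < 2:
        raise ValidationError("n_seqs must be >= 2")
    if length < 1:
        raise ValidationError("length must be >= 1")
    profile = np.broadcast_to(
        np.asarray(conservation_profile, dtype=float), (length,)
    ).copy()
    if np.any((profile < 0) | (profile > 1)):
        raise ValidationError("conservation probabilities must lie in [0, 1]")
    if not 0 <= gap_rate < 1:
        raise ValidationError("gap_rate must lie in [0, 1)")
    freqs = (
        np.full(20, 1 / 20)
        if background_freqs is None
        else np.asarray(background_freqs, dtype=float)
    )
    if freqs.shape != (20,) or abs(freqs.sum() - 1) > 1e-9 or np.any(freqs < 0):
        raise ValidationError("background_freqs must be 20 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    ancestor = rng.choice(letters, size=length, p=freqs)
    rows = []
    geo_p = 1.0 / mean_gap_length
    for i in range(n_seqs):
        copy = rng.random(length) < profile
        fresh = rng.choice(letters, size=length, p=freqs)
        seq = np.where(copy, ancestor, fresh)
        if gap_rate > 0:
            starts = np.flatnonzero(rng.random(length) < gap_rate)
            for s in starts:
                seg = rng.geometric(geo_p)
                seq[s : s + seg] = GAP
        rows.append(
            SequenceRecord(
                seq_id=f"seq{i + 1:03d}",
                gapped_residues="".join(seq),
                organism="synthetic",
            )
        )
    return Alignment(rows)


def _force_acceptor_column(
    aln: Alignment, column: int, rng: np.random.Generator, conservation: float
) -> None:
    """Overwrite non-gap letters of *column* with S/T at the given rate."""
    j = column - 1
    for row in aln.rows:
        if row.gapped_residues[j] == GAP:
            continue
        if rng.random() < conservation:
            chars = list(row.gapped_residues)
            chars[j] = _ACCEPTORS[rng.integers(len(_ACCEPTORS))]
            row.gapped_residues = "".join(chars)


def _acceptor_rows(aln: Alignment, column: int) -> list[SequenceRecord]:
    j = column - 1
    return [
        r
        for r in aln.rows
        if r.gapped_residues[j] in "STY"
    ]


def _records_at(
    aln: Alignment,
    column: int,
    count: int,
    known_function: bool,
    rng: np.random.Generator,
    source: str,
) -> list[PTMRecord]:
    rows = _acceptor_rows(aln, column)
    if len(rows) < count:
        raise ValidationError(
            f"column {column}: only {len(rows)} acceptor rows for "
            f"{count} records"
        )
    chosen = rng.choice(len(rows), size=count, replace=False)
    records = []
    for idx in sorted(int(i) for i in chosen):
        row = rows[idx]
        native = row.gapped_residues[:column].replace(GAP, "")
        pos = len(native)
        records.append(
            PTMRecord(
                protein_id=row.seq_id,
                native_pos=pos,
                residue=row.letter_at_native(pos),
                ptm_type=PTMType.phosphorylation,
                known_function=known_function,
                source=source,
            )
        )
    return records


def plant_ptms(
    aln: Alignment,
    n_hotspots: int = 5,
    ptms_per_hotspot: float = 6.0,
    n_background: int = 30,
    functional_fraction: float = 0.4,
    seed: int = 0,
    window: int = 2,
    acceptor_conservation: float = 0.95,
) -> tuple[list[PTMRecord], SyntheticTruth]:
    """Plant hotspot and background PTM records into *aln* (mutated in
    place: hotspot and reference columns are forced to high acceptor
    content). Returns the records and the ground truth."""
    rng = np.random.default_rng(seed)
    length = aln.n_columns
    margin = window + 1
    min_sep = 2 * window + 3
    eligible = list(range(margin + 1, length - margin))
    rng.shuffle(eligible)
    hotspots: list[int] = []
    for col in eligible:
        if all(abs(col - h) >= min_sep for h in hotspots):
            hotspots.append(col)
        if len(hotspots) == n_hotspots:
            break
    if len(hotspots) < n_hotspots:
        raise ValidationError(
            f"cannot place {n_hotspots} hotspots at separation {min_sep} in "
            f"{length} columns; reduce n_hotspots or window"
        )
    n_functional = round(functional_fraction * n_hotspots)
    functional = set(hotspots[:n_functional])

    records: list[PTMRecord] = []
    truth = SyntheticTruth(hotspot_columns=set(hotspots), functional_columns=functional)

    for col in hotspots:
        _force_acceptor_column(aln, col, rng, acceptor_conservation)
        pc = max(1, int(rng.poisson(ptms_per_hotspot)))
        is_func = col in functional
        if is_func:
            pc += 1  # coincident known-functional reference record
        records.extend(
            _records_at(aln, col, pc, known_function=is_func, rng=rng,
                        source="hotspot" if not is_func else "hotspot+reference")
        )
        if is_func and window >= 1:
            for ref_col in (col - window, col + window):
                _force_acceptor_column(aln, ref_col, rng, acceptor_conservation)
                rc = max(1, int(rng.poisson(ptms_per_hotspot / 2.0)))
                records.extend(
                    _records_at(aln, ref_col, rc, known_function=True,
                                rng=rng, source="reference")
                )
                truth.reference_columns.add(ref_col)

    for col in sorted(functional):
        rec = next(r for r in records
                   if build_native_column(aln, r) == col)
        truth.interface_truth.append((rec.protein_id, rec.native_pos))

    blocked = set()
    for h in hotspots:
        blocked.update(range(h - 2 * window, h + 2 * window + 1))
    blocked |= truth.reference_columns
    candidates = [
        c
        for c in range(1, length + 1)
        if c not in blocked and _acceptor_rows(aln, c)
    ]
    if len(candidates) < n_background:
        raise ValidationError(
            f"only {len(candidates)} background columns available for "
            f"{n_background}; reduce n_background"
        )
    chosen = rng.choice(len(candidates), size=n_background, replace=False)
    for idx in sorted(int(i) for i in chosen):
        col = candidates[idx]
        truth.background_columns.add(col)
        records.extend(
            _records_at(aln, col, 1, known_function=False, rng=rng,
                        source="background")
        )
    records.sort(key=lambda r: r.key)
    return records, truth


def build_native_column(aln: Alignment, record: PTMRecord) -> int:
    """Alignment column of a record's residue (convenience for tests)."""
    row = aln.row(record.protein_id)
    count = 0
    for j, ch in enumerate(row.gapped_residues):
        if ch != GAP:
            count += 1
            if count == record.native_pos:
                return j + 1
    raise ValidationError(
        f"{record.protein_id}: position {record.native_pos} beyond sequence"
    )


def simulate_structure_pair(
    n_residues_per_chain: int,
    n_contact_pairs: int,
    cutoff: float = 4.0,
    seed: int = 0,
) -> tuple[StructureChain, StructureChain, list[tuple[int, int]]]:
    """Two single-atom-per-residue (C-alpha) chains with exactly
    *n_contact_pairs* inter-chain residue pairs inside *cutoff*; all other
    inter-chain pairs are at least ``cutoff + 2`` apart."""
    if n_contact_pairs > n_residues_per_chain:
        raise ValidationError("n_contact_pairs exceeds chain length")
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    rng = np.random.default_rng(seed)
    spacing = math.sqrt(max((cutoff + 2.0) ** 2 - 2.5**2, 1.0)) + 0.5
    far = 10.0 * (cutoff + 2.0)
    letters = list(_AA3.values())

    def _residue(number: int, x: float, y: float, z: float) -> Residue:
        name = letters[rng.integers(len(letters))]
        return Residue(number, name, [Atom("CA", x, y, z)])

    chain_a = [
        _residue(i + 1, i * spacing, 0.0, 0.0)
        for i in range(n_residues_per_chain)
    ]
    contact_a = sorted(
        int(i) + 1
        for i in rng.choice(n_residues_per_chain, size=n_contact_pairs, replace=False)
    )
    contact_b = sorted(
        int(i) + 1
        for i in rng.choice(n_residues_per_chain, size=n_contact_pairs, replace=False)
    )
    pair_of_b = dict(zip(contact_b, contact_a))
    chain_b = []
    for i in range(n_residues_per_chain):
        number = i + 1
        if number in pair_of_b:
            partner = pair_of_b[number]
            d = rng.uniform(2.5, cutoff)
            chain_b.append(_residue(number, (partner - 1) * spacing, 0.0, d))
        else:
            chain_b.append(_residue(number, i * spacing, far, 0.0))
    pairs = sorted(zip(contact_a, contact_b))
    return (
        StructureChain("A", chain_a),
        StructureChain("B", chain_b),
        pairs,
    )


def write_structure_pair(
    a: StructureChain, b: StructureChain, path: str | Path
) -> None:
    """Write two chains as fixed-column PDB ATOM records."""
    serial = 0
    lines = []
    for chain in (a, b):
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name.strip()
                padded = f" {name:<3s}" if len(name) < 4 else name
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s} {res.name:>3s} "
                    f"{chain.chain_id}{res.number:4d}    "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# recovery harness


def recovery_trial(
    seed: int,
    n_seqs: int = 40,
    length: int = 300,
    n_hotspots: int = 5,
    ptms_per_hotspot: float = 6.0,
    n_background: int = 30,
    functional_fraction: float = 0.4,
    window: int = 2,
    baseline_conservation: float = 0.6,
    gap_rate: float = 0.05,
    weights: Optional[Weights] = None,
) -> tuple[SyntheticTruth, list[ScoredMAP]]:
    """One end-to-end synthetic run: simulate, plant, featurize, rank."""
    aln = simulate_family(
        n_seqs, length, baseline_conservation, gap_rate=gap_rate, seed=seed
    )
    records, truth = plant_ptms(
        aln,
        n_hotspots=n_hotspots,
        ptms_per_hotspot=ptms_per_hotspot,
        n_background=n_background,
        functional_fraction=functional_fraction,
        seed=seed + 1,
        window=window,
    )
    rmaps = build_residue_maps(aln)
    maps = build_maps(records, rmaps)
    by_protein: dict[str, set[int]] = {}
    for pid, pos in truth.interface_truth:
        by_protein.setdefault(pid, set()).add(pos)
    interfaces = [
        InterfaceSet(pid, positions) for pid, positions in by_protein.items()
    ]
    compute_features(
        aln, maps, rmaps, interfaces=interfaces, window=window, scope="all"
    )
    scored = rank_maps(score_maps(maps, weights or Weights()))
    bin_scores(scored, 5)
    return truth, scored


def recovery_rates(
    seeds: Sequence[int], top_hotspot: int = 10, top_functional: int = 2, **kwargs
) -> tuple[float, float]:
    """Fractions of runs where (a) every planted hotspot ranks within
    *top_hotspot* and (b) the functional hotspots hold the *top_functional*
    first ranks."""
    hot_ok = func_ok = 0
    for seed in seeds:
        truth, scored = recovery_trial(seed, **kwargs)
        ranks = {s.column: s.rank for s in scored}
        if all(ranks[c] <= top_hotspot for c in truth.hotspot_columns):
            hot_ok += 1
        if all(ranks[c] <= top_functional for c in truth.functional_columns):
            func_ok += 1
    n = len(seeds)
    return hot_ok / n, func_ok / n
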