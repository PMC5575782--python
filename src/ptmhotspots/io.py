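"""Reading, validation and writing of family alignments, PTM site tables,
region annotations and the analysis configuration.

Positions are 1-based throughout; intervals are inclusive on both ends.
Aligned FASTA uses ``-`` as the gap character ('.' is accepted on input and
normalized). PTM tables are tab-separated with a header row.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ" + GAP)


class ValidationError(ValueError):
    """Input failed a structural or provenance check."""


class AlignmentShapeError(ValidationError):
    """Rows of an alignment do not share a common length."""


class ProvenanceError(ValidationError):
    """A PTM record does not match the sequence it claims to annotate."""


@dataclass
class SequenceRecord:
    """One gapped row of a family alignment."""

    seq_id: str
    gapped_residues: str
    organism: str = ""
    is_query: bool = False

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValidationError("sequence record with empty seq_id")
        if not self.gapped_residues:
            raise ValidationError(f"{self.seq_id}: empty sequence")
        self.gapped_residues = self.gapped_residues.upper().replace(".", GAP)
        bad = set(self.gapped_residues) - _ALLOWED
        if bad:
            raise ValidationError(
                f"{self.seq_id}: illegal characters {sorted(bad)!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.gapped_residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)

    def letter_at_native(self, native_pos: int) -> str:
        seq = self.ungapped
        if not 1 <= native_pos <= len(seq):
            raise ValidationError(
                f"{self.seq_id}: native position {native_pos} outside 1..{len(seq)}"
            )
        return seq[native_pos - 1]


@dataclass
class Alignment:
    """An ordered set of equal-length gapped rows."""

    rows: list[SequenceRecord]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment with no rows")
        lengths = {len(r.gapped_residues) for r in self.rows}
        if len(lengths) != 1:
            for r in self.rows:
                if len(r.gapped_residues) != len(self.rows[0].gapped_residues):
                    raise AlignmentShapeError(
                        f"row {r.seq_id!r} has length {len(r.gapped_residues)}, "
                        f"expected {len(self.rows[0].gapped_residues)}"
                    )
        self.n_columns = lengths.pop()
        ids = [r.seq_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate seq_id(s): {dupes}")
        self._index = {r.seq_id: r for r in self.rows}

    def row(self, seq_id: str) -> SequenceRecord:
        try:
            return self._index[seq_id]
        except KeyError:
            raise ValidationError(f"unknown seq_id {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def column(self, col: int) -> str:
        """Letters of 1-based column *col*, one per row."""
        if not 1 <= col <= self.n_columns:
            raise ValidationError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r.gapped_residues[col - 1] for r in self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.rows]

    def query_rows(self) -> list[SequenceRecord]:
        return [r for r in self.rows if r.is_query]


class PTMType(str, enum.Enum):
    phosphorylation = "phosphorylation"
    ubiquitination = "ubiquitination"
    acetylation = "acetylation"
    methylation = "methylation"
    other = "other"

    @classmethod
    def parse(cls, text: str) -> "PTMType":
        t = str(text).strip().lower()
        aliases = {
            "phospho": cls.phosphorylation,
            "p": cls.phosphorylation,
            "ubiquitin": cls.ubiquitination,
            "ubiquitylation": cls.ubiquitination,
            "acetyl": cls.acetylation,
            "methyl": cls.methylation,
        }
        if t in cls._value2member_map_:
            return cls(t)
        if t in aliases:
            return aliases[t]
        # dbPTM-style tables carry dozens of modification types
        return cls.other


@dataclass(frozen=True)
class PTMRecord:
    """One experimentally observed modification at a native residue."""

    protein_id: str
    native_pos: int
    residue: str
    ptm_type: PTMType
    known_function: bool = False
    evidence: str = ""
    source: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.native_pos, self.ptm_type.value)


class RegionScope(str, enum.Enum):
    native = "native"
    alignment = "alignment"


@dataclass(frozen=True)
class RegionAnnotation:
    """A named interval, either on one protein's native coordinates or on
    alignment columns."""

    name: str
    scope: RegionScope
    start: int
    end: int
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"region {self.name}: start {self.start} > end {self.end}"
            )
        if self.scope is RegionScope.native and not self.protein_id:
            raise ValidationError(
                f"region {self.name}: native scope requires a protein_id"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class Weights:
    """Conditional multipliers of the Integrative Score.

    ``w1`` applies when a MAP has at least one neighboring known-function
    MAP (scaled by the neighbor count unless ``nkc_mode='binary'``); ``w2``
    applies when the MAP resides at a protein-protein interface. When the
    condition is absent the factor is 1, so missing evidence never
    annihilates the score.
    """

    w1: float = 2.0
    w2: float = 2.0

    def __post_init__(self) -> None:
        if self.w1 < 1 or self.w2 < 1:
            raise ValidationError("weight factors must be >= 1")


@dataclass
class AnalysisConfig:
    window: int = 2                # cluster half-width, alignment columns
    interface_cutoff: float = 4.0  # heavy-atom contact distance, Angstrom
    crosstalk_window: int = 5      # phospho-ubiquitin proximity, residues
    weights: Weights = field(default_factory=Weights)
    n_bins: int = 5
    seed: int = 0
    nkc_mode: str = "count"        # 'count' or 'binary'
    include_tyrosine_candidates: bool = False
    gap_open: float = -10.0
    gap_extend: float = -0.5
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValidationError("window must be >= 0")
        if self.interface_cutoff <= 0:
            raise ValidationError("interface_cutoff must be > 0")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.nkc_mode not in ("count", "binary"):
            raise ValidationError("nkc_mode must be 'count' or 'binary'")
        if isinstance(self.weights, dict):
            self.weights = Weights(**self.weights)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment(
    path: str | Path,
    query_ids: Optional[Iterable[str]] = None,
) -> Alignment:
    """Read an aligned FASTA file.

    Lowercase letters are uppercased and '.' gaps become '-'. Rows named in
    *query_ids* are flagged as members of the focal (query) sub-family.
    """
    queries = set(query_ids or ())
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append(
            SequenceRecord(
                seq_id=rec.id,
                gapped_residues=str(rec.seq),
                is_query=rec.id in queries,
            )
        )
    if not rows:
        raise ValidationError(f"{path}: no FASTA records found")
    return Alignment(rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        _BioSeqRecord(Seq(r.gapped_residues), id=r.seq_id, description="")
        for r in aln.rows
    ]
    SeqIO.write(records, str(path), "fasta")


_PTM_REQUIRED = ["protein_id", "native_pos", "residue", "ptm_type", "known_function"]
_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value, context: str) -> bool:
    t = str(value).strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY or t == "nan":
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


def read_ptm_table(path: str | Path, aln: Alignment) -> list[PTMRecord]:
    """Read and validate a PTM site table against *aln*.

    Every record must name a sequence present in the alignment, lie within
    its ungapped length, and carry the residue letter actually found there.
    Exact duplicates (same protein, position and type) collapse to a single
    record whose known-function flag is the OR of the duplicates; evidence
    and source strings are merged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in _PTM_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    merged: dict[tuple, dict] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"].strip()
        if pid not in aln:
            raise ValidationError(f"{path}: unknown protein_id {pid!r}")
        seq = aln.row(pid)
        try:
            pos = int(row["native_pos"])
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer native_pos {row['native_pos']!r} for {pid}"
            ) from None
        residue = row["residue"].strip().upper()
        found = seq.letter_at_native(pos)
        if residue != found:
            raise ProvenanceError(
                f"{pid} position {pos}: table claims residue {residue!r} "
                f"but the sequence carries {found!r}"
            )
        ptype = PTMType.parse(row["ptm_type"])
        kf = _parse_bool(row["known_function"], f"{pid}:{pos}")
        key = (pid, pos, ptype.value)
        slot = merged.setdefault(
            key,
            {
                "protein_id": pid,
                "native_pos": pos,
                "residue": residue,
                "ptm_type": ptype,
                "known_function": False,
                "evidence": set(),
                "source": set(),
            },
        )
        slot["known_function"] = slot["known_function"] or kf
        for col in ("evidence", "source"):
            val = str(row.get(col, "")).strip()
            if val:
                slot[col].add(val)
    records = [
        PTMRecord(
            protein_id=s["protein_id"],
            native_pos=s["native_pos"],
            residue=s["residue"],
            ptm_type=s["ptm_type"],
            known_function=s["known_function"],
            evidence=";".join(sorted(s["evidence"])),
            source=";".join(sorted(s["source"])),
        )
        for s in merged.values()
    ]
    records.sort(key=lambda r: r.key)
    return records


def write_ptm_table(records: Iterable[PTMRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "native_pos": r.native_pos,
                "residue": r.residue,
                "ptm_type": r.ptm_type.value,
                "known_function": int(r.known_function),
                "evidence": r.evidence,
                "source": r.source,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(
    path: str | Path, aln: Optional[Alignment] = None
) -> list[RegionAnnotation]:
    """Read a region annotation table (``name scope protein_id start end``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = ["name", "scope", "protein_id", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    regions = []
    for _, row in df.iterrows():
        scope = RegionScope(row["scope"].strip().lower())
        pid = row["protein_id"].strip() or None
        if pid in ("-", "."):
            pid = None
        region = RegionAnnotation(
            name=row["name"].strip(),
            scope=scope,
            protein_id=pid,
            start=int(row["start"]),
            end=int(row["end"]),
        )
        if aln is not None and scope is RegionScope.native:
            if region.protein_id not in aln:
                raise ValidationError(
                    f"region {region.name}: unknown protein_id {region.protein_id!r}"
                )
            length = aln.row(region.protein_id).ungapped_length
            if region.end > length:
                raise ValidationError(
                    f"region {region.name}: interval {region.start}-{region.end} "
                    f"exceeds ungapped length {length} of {region.protein_id}"
                )
        regions.append(region)
    return regions


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
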