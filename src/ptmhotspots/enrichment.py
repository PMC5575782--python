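"""Region enrichment of observed phosphosites over random expectation, and
conservation comparison between phosphosite columns and the
phospho-capable background.

The enrichment statistic is the standard observed/expected ratio

    fold = (k / n) / (K / N)

with k observed sites in the region, n observed sites in scope, K candidate
acceptor positions in the region and N candidates in scope. A region that
contains every candidate therefore folds to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .features import PHOSPHO_ACCEPTORS, column_conservation
from .io import (
    Alignment,
    PTMRecord,
    PTMType,
    RegionAnnotation,
    RegionScope,
    SequenceRecord,
    ValidationError,
)


@dataclass
class EnrichmentResult:
    region: str
    k: int  # observed sites in region
    n: int  # observed sites in scope
    K: int  # candidate positions in region
    N: int  # candidate positions in scope
    fold: float
    undefined: bool = False


def candidate_positions(
    member: SequenceRecord,
    residues: str = "ST",
    region: Optional[RegionAnnotation] = None,
) -> list[int]:
    """Native positions of *member* carrying one of *residues* (optionally
    restricted to a native-scope region)."""
    if region is not None and region.scope is not RegionScope.native:
        raise ValidationError("candidate_positions needs a native-scope region")
    allowed = set(residues)
    seq = member.ungapped
    positions = [
        i + 1
        for i, ch in enumerate(seq)
        if ch in allowed
        and (region is None or region.contains(i + 1))
    ]
    return positions


def enrichment_fold(
    sites: Iterable[PTMRecord] | Iterable[int],
    candidates: Sequence[int],
    region: RegionAnnotation,
) -> EnrichmentResult:
    """Fold enrichment of observed sites in *region* over uniform
    expectation across the candidate positions.

    *sites* may be PTM records (their native positions are used) or bare
    positions; every site must be a candidate. Degenerate denominators
    (no candidates in the region, or no observed sites) yield a flagged
    undefined result rather than an exception.
    """
    positions = sorted(
        {
            s.native_pos if isinstance(s, PTMRecord) else int(s)
            for s in sites
        }
    )
    cand = sorted(set(candidates))
    stray = [p for p in positions if p not in set(cand)]
    if stray:
        raise ValidationError(
            f"observed site(s) {stray} are not candidate positions"
        )
    n = len(positions)
    N = len(cand)
    k = sum(1 for p in positions if region.contains(p))
    K = sum(1 for p in cand if region.contains(p))
    if K == 0 or n == 0 or N == 0:
        return EnrichmentResult(region.name, k, n, K, N, float("nan"), True)
    fold = (k / n) / (K / N)
    return EnrichmentResult(region.name, k, n, K, N, fold, False)


class ConservationComparison(NamedTuple):
    site_trc: float
    site_pac: float
    background_trc: float
    background_pac: float
    n_site_columns: int
    n_background_columns: int
    undefined: bool


def conservation_comparison(
    aln: Alignment,
    site_columns: Iterable[int],
    scope: str = "query",
    region: Optional[RegionAnnotation] = None,
    background_columns: Optional[Iterable[int]] = None,
) -> ConservationComparison:
    """Mean TRC and PAC over phosphosite columns versus the background of
    all other columns harboring at least one phospho-acceptor residue.

    The background defaults to every column (within *region*, if given,
    which must be alignment-scoped) whose scope rows carry at least one
    S/T/Y, minus the site columns. An explicit background must be disjoint
    from the site set. Returns NaN means with the undefined flag when the
    background is empty.
    """
    sites = sorted(set(site_columns))
    if not sites:
        raise ValidationError("no site columns given")
    if region is not None and region.scope is not RegionScope.alignment:
        raise ValidationError(
            "conservation_comparison needs an alignment-scope region"
        )
    if background_columns is None:
        rows = aln.query_rows() if scope == "query" else aln.rows
        if not rows:
            raise ValidationError("scope='query' but no rows flagged is_query")
        background = []
        for col in range(1, aln.n_columns + 1):
            if region is not None and not region.contains(col):
                continue
            if col in sites:
                continue
            letters = (r.gapped_residues[col - 1] for r in rows)
            if any(ch in PHOSPHO_ACCEPTORS for ch in letters):
                background.append(col)
    else:
        background = sorted(set(background_columns))
        overlap = set(background) & set(sites)
        if overlap:
            raise ValidationError(
                f"background overlaps site columns: {sorted(overlap)}"
            )
    def _means(columns: list[int]) -> tuple[float, float]:
        if not columns:
            return float("nan"), float("nan")
        cons = [column_conservation(aln, c, scope=scope) for c in columns]
        return (
            sum(c.trc for c in cons) / len(cons),
            sum(c.pac for c in cons) / len(cons),
        )

    site_trc, site_pac = _means(sites)
    bg_trc, bg_pac = _means(background)
    return ConservationComparison(
        site_trc,
        site_pac,
        bg_trc,
        bg_pac,
        len(sites),
        len(background),
        undefined=not background,
    )


def enrichment_report(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fold": round(r.fold, 6) if not r.undefined else "",
                "flag": "undefined" if r.undefined else "ok",
            }
            for r in results
        ]
    )
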