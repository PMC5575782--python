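"""The Integrative Score: a multiplicative prioritization of MAPs.

``IS = CPC * PC * PRC * W1(NKC) * W2(PPI)``

where the two conditional weight factors are inactive (equal to 1) when
their evidence channel is absent: W1 activates when the MAP has at least
one neighboring known-function MAP (by default scaling linearly with the
neighbor count), W2 activates when the MAP resides at a protein-protein
interface. A MAP with no modifications or no conservable acceptor residue
scores zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .features import FeatureVector, serialize_members
from .io import ValidationError, Weights
from .map_builder import MAP

__all__ = ["Weights", "ScoredMAP", "integrative_score", "score_maps",
           "rank_maps", "bin_scores", "rank_table"]


@dataclass
class ScoredMAP:
    map: MAP
    IS: float
    rank: Optional[int] = None
    bin: Optional[int] = None

    @property
    def column(self) -> int:
        return self.map.column

    @property
    def features(self) -> FeatureVector:
        assert self.map.features is not None
        return self.map.features


def integrative_score(
    fv: FeatureVector, w: Weights, nkc_mode: str = "count"
) -> float:
    """Integrative Score of one feature vector.

    With ``nkc_mode='count'`` the neighbor factor is ``w1 * NKC`` when
    NKC > 0; with ``'binary'`` it is ``w1`` whenever NKC > 0.
    """
    if fv.cpc < 0 or fv.pc < 0 or fv.prc < 0 or fv.nkc < 0:
        raise ValidationError("negative feature value")
    if nkc_mode == "count":
        f1 = w.w1 * fv.nkc if fv.nkc > 0 else 1.0
    elif nkc_mode == "binary":
        f1 = w.w1 if fv.nkc > 0 else 1.0
    else:
        raise ValidationError(f"unknown nkc_mode {nkc_mode!r}")
    f2 = w.w2 if fv.ppi else 1.0
    return float(fv.cpc) * float(fv.pc) * fv.prc * f1 * f2


def score_maps(
    maps: Sequence[MAP], w: Optional[Weights] = None, nkc_mode: str = "count"
) -> list[ScoredMAP]:
    w = w or Weights()
    scored = []
    for m in maps:
        if m.features is None:
            raise ValidationError(f"MAP at column {m.column} has no features")
        s = integrative_score(m.features, w, nkc_mode=nkc_mode)
        m.score = s
        scored.append(ScoredMAP(map=m, IS=s))
    return scored


def rank_maps(scored: Sequence[ScoredMAP]) -> list[ScoredMAP]:
    """Rank MAPs by descending IS; ties break by higher CPC, then higher
    PC, then lower column index. Deterministic and input-order-independent."""
    out = sorted(
        scored,
        key=lambda s: (-s.IS, -s.features.cpc, -s.features.pc, s.column),
    )
    for r, s in enumerate(out, start=1):
        s.rank = r
    return out


def bin_scores(scored: Sequence[ScoredMAP], n_bins: int) -> list[ScoredMAP]:
    """Assign quantile bins for structural color coding.

    Zero scores get bin 0. Positive scores are split into *n_bins*
    empirical-CDF bins (``bin = ceil(F * n_bins)`` with F the fraction of
    positive scores <= the MAP's score), so equal scores always share a bin
    and the highest scores land in bin ``n_bins``.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    positive = sorted(s.IS for s in scored if s.IS > 0)
    npos = len(positive)
    import bisect

    for s in scored:
        if s.IS <= 0:
            s.bin = 0
        else:
            frac = bisect.bisect_right(positive, s.IS) / npos
            s.bin = max(1, math.ceil(frac * n_bins - 1e-9))
    return list(scored)


def rank_table(scored: Sequence[ScoredMAP]) -> pd.DataFrame:
    """Rank table TSV layout: one row per MAP, best rank first."""
    rows = []
    for s in sorted(scored, key=lambda x: (x.rank if x.rank is not None else 0)):
        f = s.features
        rows.append(
            {
                "rank": s.rank,
                "column": s.column,
                "IS": round(s.IS, 6),
                "bin": s.bin,
                "PC": f.pc,
                "CPC": f.cpc,
                "PRC": round(f.prc, 6),
                "NKC": f.nkc,
                "PPI": int(f.ppi),
                "member_ptms": serialize_members(s.map),
            }
        )
    return pd.DataFrame(rows)
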