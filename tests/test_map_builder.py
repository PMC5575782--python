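"""Residue maps, MAP grouping and the profile-to-profile merger."""


import numpy as np
import pytest

from ptmhotspots import (
    Alignment,
    SequenceRecord,
    ValidationError,
    build_maps,
    build_residue_map,
    build_residue_maps,
    extract_profile,
    profile_align,
)
from ptmhotspots.map_builder import (
    GapColumnError,
    column_frequencies,
    load_matrix,
    score_merged,
)

from conftest import phospho


class TestResidueMap:
    def test_gapped_row(self):
        rmap = build_residue_map(SequenceRecord("x", "MK--S"))
        assert rmap.to_column(3) == 5
        assert rmap.to_native(5) == 3

    def test_identity_on_ungapped_row(self):
        rmap = build_residue_map(SequenceRecord("x", "MKS"))
        assert [rmap.to_column(i) for i in (1, 2, 3)] == [1, 2, 3]

    def test_gap_column_query_raises(self):
        rmap = build_residue_map(SequenceRecord("x", "MK--S"))
        with pytest.raises(GapColumnError):
            rmap.to_native(3)

    def test_out_of_domain_raises(self):
        rmap = build_residue_map(SequenceRecord("x", "MK--S"))
        with pytest.raises(ValidationError):
            rmap.to_column(4)

    def test_bijection(self):
        row = SequenceRecord("x", "-MA--KLS-T--")
        rmap = build_residue_map(row)
        for i in range(1, row.ungapped_length + 1):
            assert rmap.to_native(rmap.to_column(i)) == i


class TestBuildMaps:
    def test_same_column_groups(self):
        aln = Alignment(
            [SequenceRecord("P1", "AAS-"), SequenceRecord("P2", "-ASK")]
        )
        rmaps = build_residue_maps(aln)
        maps = build_maps([phospho("P1", 3), phospho("P2", 2)], rmaps)
        assert len(maps) == 1
        assert len(maps[0].ptms) == 2

    def test_distinct_columns_stay_apart(self, toy_alignment):
        rmaps = build_residue_maps(toy_alignment)
        maps = build_maps(
            [phospho("P1", 5), phospho("P1", 6, "T"), phospho("P1", 7, "Y")], rmaps
        )
        assert [m.column for m in maps] == [5, 6, 7]

    def test_hand_mapped_toy_family(self):
        """Five PTMs on a 4-row MSA, grouping checked by hand."""
        aln = Alignment(
            [
                SequenceRecord("A", "MS-TKS"),
                SequenceRecord("B", "MSAT-S"),
                SequenceRecord("C", "M-ATKS"),
                SequenceRecord("D", "MSAT--"),
            ]
        )
        rmaps = build_residue_maps(aln)
        ptms = [
            phospho("A", 2),        # column 2
            phospho("B", 2),        # column 2
            phospho("B", 4, "T"),   # column 4
            phospho("C", 3, "T"),   # column 4
            phospho("A", 5, "S"),   # column 6
        ]
        maps = build_maps(ptms, rmaps)
        assert [(m.column, len(m.ptms)) for m in maps] == [(2, 2), (4, 2), (6, 1)]

    def test_record_conservation(self, toy_alignment):
        rmaps = build_residue_maps(toy_alignment)
        ptms = [phospho("P1", 5), phospho("P2", 5), phospho("P1", 6, "T")]
        maps = build_maps(ptms, rmaps)
        assert sum(len(m.ptms) for m in maps) == len(ptms)


# ---------------------------------------------------------------------------
# profile merge


def _aln(*seqs, prefix="s"):
    return Alignment(
        [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]
    )


def oracle_best_score(pair, gap_open, gap_extend):
    """Exhaustive enumeration of every monotone column pairing, scoring
    each path independently (affine gap runs found by scanning the op
    string). Independent of the DP recurrences."""
    m, n = pair.shape
    best = -np.inf

    def walk(i, j, ops):
        nonlocal best
        if i == m and j == n:
            score = 0.0
            prev = None
            ii = jj = 0
            for op in ops:
                if op == "M":
                    score += pair[ii, jj]
                    ii += 1
                    jj += 1
                    prev = None
                else:
                    score += gap_extend if prev == op else gap_open
                    prev = op
                    if op == "X":
                        ii += 1
                    else:
                        jj += 1
            best = max(best, score)
            return
        if i < m and j < n:
            walk(i + 1, j + 1, ops + ["M"])
        if i < m:
            walk(i + 1, j, ops + ["X"])
        if j < n:
            walk(i, j + 1, ops + ["Y"])

    walk(0, 0, [])
    return best


class TestProfileAlign:
    def test_identical_singletons_no_new_gaps(self):
        merged = profile_align(_aln("RGS"), _aln("RGS", prefix="t"))
        assert merged.n_columns == 3
        assert all("-" not in r.gapped_residues for r in merged.rows)

    def test_single_insertion(self):
        a, b = _aln("RGS"), _aln("RAGS", prefix="t")
        merged = profile_align(a, b)
        assert merged.n_columns == 4
        assert merged.row("s0").gapped_residues == "R-GS"
        assert merged.row("t0").gapped_residues == "RAGS"

    def test_strip_recovers_each_profile(self):
        a = _aln("RGSKL", "RG-KL")
        b = _aln("MRGEESKL", prefix="t")
        merged = profile_align(a, b)
        back_a = extract_profile(merged, a.ids)
        back_b = extract_profile(merged, b.ids)
        assert [r.gapped_residues for r in back_a.rows] == ["RGSKL", "RG-KL"]
        assert [r.gapped_residues for r in back_b.rows] == ["MRGEESKL"]

    def test_shared_ids_rejected(self):
        with pytest.raises(ValidationError):
            profile_align(_aln("RGS"), _aln("RGS"))

    def test_matches_exhaustive_oracle_on_small_profiles(self):
        rng = np.random.default_rng(42)
        S = load_matrix()
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            la, lb = rng.integers(1, 7), rng.integers(1, 7)
            a = _aln(
                *(
                    "".join(letters[k] for k in rng.integers(0, 20, la))
                    for _ in range(2)
                )
            )
            b = _aln(
                *(
                    "".join(letters[k] for k in rng.integers(0, 20, lb))
                    for _ in range(2)
                ),
                prefix="t",
            )
            pair = column_frequencies(a) @ S @ column_frequencies(b).T
            expected = oracle_best_score(pair, -10.0, -0.5)
            merged = profile_align(a, b)
            got = score_merged(merged, set(a.ids))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_symmetric_in_profile_order(self):
        rng = np.random.default_rng(3)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        a = _aln("".join(letters[k] for k in rng.integers(0, 20, 12)))
        b = _aln("".join(letters[k] for k in rng.integers(0, 20, 15)), prefix="t")
        ab = profile_align(a, b)
        ba = profile_align(b, a)
        assert score_merged(ab, set(a.ids)) == pytest.approx(
            score_merged(ba, set(b.ids))
        )
        assert [r.gapped_residues for r in extract_profile(ab, a.ids).rows] == [
            r.gapped_residues for r in extract_profile(ba, a.ids).rows
        ]

    def test_ptm_columns_stable_through_merge(self, rgs_demo):
        """A record's column before the merge translates exactly to its
        column after the merge (through the inserted gap columns)."""
        from ptmhotspots import read_alignment, read_ptm_table

        plant = read_alignment(rgs_demo["plant_alignment"])
        fam = read_alignment(rgs_demo["family_alignment"])
        merged = profile_align(plant, fam)
        records = read_ptm_table(rgs_demo["plant_sites"], plant)
        pre = build_residue_maps(plant)
        post = build_residue_maps(merged)
        # columns of the original plant profile, in merged coordinates
        plant_rows = [merged.row(i) for i in plant.ids]
        kept = [
            j + 1
            for j in range(merged.n_columns)
            if any(r.gapped_residues[j] != "-" for r in plant_rows)
        ]
        for rec in records:
            before = pre[rec.protein_id].to_column(rec.native_pos)
            after = post[rec.protein_id].to_column(rec.native_pos)
            assert kept[before - 1] == after

    def test_deterministic(self):
        a = _aln("RGSKL", "RG-KL")
        b = _aln("MRGEESKL", prefix="t")
        r1 = profile_align(a, b)
        r2 = profile_align(a, b)
        assert [x.gapped_residues for x in r1.rows] == [
            x.gapped_residues for x in r2.rows
        ]


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60)
@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", min_size=1, max_size=40).filter(
        lambda s: s.replace("-", "")
    )
)
def test_residue_map_is_a_bijection(gapped):
    rmap = build_residue_map(SequenceRecord("x", gapped))
    length = len(gapped.replace("-", ""))
    cols = [rmap.to_column(i) for i in range(1, length + 1)]
    assert cols == sorted(set(cols))  # strictly increasing
    assert all(rmap.to_native(c) == i + 1 for i, c in enumerate(cols))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=8),
        min_size=1,
        max_size=3,
    ),
    st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=8),
        min_size=1,
        max_size=3,
    ),
)
def test_merge_always_recovers_both_profiles(seqs_a, seqs_b):
    la = max(len(s) for s in seqs_a)
    lb = max(len(s) for s in seqs_b)
    a = _aln(*(s.ljust(la, s[-1]) for s in seqs_a))
    b = _aln(*(s.ljust(lb, s[-1]) for s in seqs_b), prefix="t")
    merged = profile_align(a, b)
    assert [r.gapped_residues for r in extract_profile(merged, a.ids).rows] == [
        r.gapped_residues for r in a.rows
    ]
    assert [r.gapped_residues for r in extract_profile(merged, b.ids).rows] == [
        r.gapped_residues for r in b.rows
    ]
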