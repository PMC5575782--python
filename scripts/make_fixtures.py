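"""Regenerate the packaged synthetic RGS fixtures (deterministic).

The site tables transcribe curated native positions; the sequences are
synthetic stand-ins built around a master coordinate frame so that every
annotated site carries the right residue, the AtRGS1 cytoplasmic region
carries exactly 29 S/T candidates (13 of them within positions 284-417),
and the non-plant members' sites fall at family-coincident columns.

Run from the repository root:  python scripts/make_fixtures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ptmhotspots.io import AMINO_ACIDS  # noqa: E402
from ptmhotspots.structure import Atom, Residue, StructureChain  # noqa: E402
from ptmhotspots.synthetic import _AA3, write_structure_pair  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "src" / "ptmhotspots" / "data"

OFF = 40          # master col = plant native (AtRGS1) + OFF
MASTER = 500      # master frame width
AT_LEN = 459
GM_GAP_PLANT_COL = 300  # GmRGS2 native p -> plant col p (p<300) or p+1

NON_ST = [a for a in AMINO_ACIDS if a not in "ST"]

AT_REQUIRED = {339: "S", 365: "S", 375: "T", 379: "T", 406: "S", 411: "K",
               417: "S", 428: "S", 436: "S", 453: "S"}
# extra S/T filler so that AtRGS1 has 13 S/T in 284-417 and 16 in 418-459
AT_FILLER_FIXED = {338: "S", 405: "S", 429: "T", 438: "T"}
GM_REQUIRED = {267: "T", 269: "S", 277: "S", 405: "S", 410: "K",
               428: "T", 437: "T"}

PLANT_SITE_COLS = [267, 269, 277, 339, 365, 375, 379, 406, 417, 428, 429,
                   436, 438, 453]

# non-plant members: (name, length, master start col, {native: letter})
MAMMALS = [
    ("hRGS2",  211, 263, {46: "S"}),
    ("hRGS18", 235, 261, {216: "S", 218: "S"}),
    ("hRGS10", 173, 311, {168: "S", 136: "K"}),
    ("rRGS4",  205, 276, {103: "S"}),
    ("hRGS5",  181, 280, {166: "S"}),
    ("hRGS7",  460, 13,  {434: "S"}),
    ("hRGS16", 202, 280, {168: "Y"}),
]


def build_at_sequence(rng) -> list[str]:
    seq = [""] * (AT_LEN + 1)  # 1-based
    for pos, letter in {**AT_REQUIRED, **AT_FILLER_FIXED}.items():
        seq[pos] = letter
    # remaining S/T filler inside 284-417 (need 13 total; 6 required + 2 fixed)
    free = [p for p in range(284, 417) if not seq[p] and p != 411]
    for p in rng.choice(free, size=5, replace=False):
        seq[p] = "ST"[rng.integers(2)]
    # remaining S/T filler inside 418-459 (need 16 total; 3 required + 2 fixed)
    free = [p for p in range(418, 460) if not seq[p]]
    for p in rng.choice(free, size=11, replace=False):
        seq[p] = "ST"[rng.integers(2)]
    # everything else in the cytoplasmic region avoids S/T; the rest is free
    for p in range(1, AT_LEN + 1):
        if seq[p]:
            continue
        if 284 <= p <= 459:
            seq[p] = NON_ST[rng.integers(len(NON_ST))]
        else:
            seq[p] = AMINO_ACIDS[rng.integers(20)]
    # conserved acceptor columns shared with GmRGS2 sites (N-terminal side)
    seq[267], seq[269], seq[277] = "T", "S", "S"
    return seq


def main() -> None:
    rng = np.random.default_rng(7)
    OUT.mkdir(parents=True, exist_ok=True)

    at = build_at_sequence(rng)
    at[268] = "S"  # column shared with the hRGS2-S46 site
    at[407] = "Y"  # column shared with the hRGS16-Y168 site

    # master ancestor: AtRGS1 letters shifted by OFF, random elsewhere
    ancestor = [AMINO_ACIDS[rng.integers(20)] for _ in range(MASTER + 1)]
    for p in range(1, AT_LEN + 1):
        ancestor[p + OFF] = at[p]
    # GmRGS2: native p -> plant col p (p < 300) else p + 1
    gm = [""] * (AT_LEN + 1)
    for p in range(1, AT_LEN + 1):
        plant_col = p if p < GM_GAP_PLANT_COL else p + 1
        anc = ancestor[plant_col + OFF]
        gm[p] = anc if rng.random() < 0.88 else AMINO_ACIDS[rng.integers(20)]
    for pos, letter in GM_REQUIRED.items():
        gm[pos] = letter

    at_row = "".join(at[1:]) + "-"                       # plant cols 1..460
    gm_row = ("".join(gm[1:GM_GAP_PLANT_COL]) + "-"
              + "".join(gm[GM_GAP_PLANT_COL:]))
    assert len(at_row) == len(gm_row) == 460

    plant_rows = [("AtRGS1", at_row), ("GmRGS2", gm_row)]
    site_plant_cols = set(PLANT_SITE_COLS)
    for i in range(6):
        chars = []
        for col in range(1, 461):
            anc = ancestor[col + OFF]
            copy_p = 0.97 if col in site_plant_cols else 0.85
            if col == 411:
                chars.append("K" if i < 5 else "R")  # 7 of 8 rows keep the lysine
            elif rng.random() < copy_p:
                chars.append(anc)
            else:
                chars.append(AMINO_ACIDS[rng.integers(20)])
        # three gap segments per row, away from every annotated column
        for _ in range(3):
            start = int(rng.integers(10, 245))
            length = int(rng.integers(3, 12))
            for j in range(start, min(start + length, 256)):
                chars[j - 1] = "-"
        plant_rows.append((f"SynPlant{i + 1}", "".join(chars)))

    with open(OUT / "synthetic_plant_rgs_alignment.fasta", "w") as fh:
        for name, row in plant_rows:
            fh.write(f">{name}\n{row}\n")

    # --- plant phosphosite table -------------------------------------------
    at_sites = [
        (339, "BRL3"), (365, "BRL3;PEPR1"), (375, "PEPR1"), (379, "PEPR1"),
        (417, "BAK1"), (428, "BAK1;BRL3;PEPR1;WNK8"), (436, "WNK8"),
        (453, "BRL3"),
    ]
    at_known = {428, 436}
    gm_sites = [(267, "NFR1"), (269, "NFR1"), (277, "NFR1"), (405, "NFR1"),
                (428, "NFR1"), (437, "NFR1")]
    gm_known = {267, 437}
    lines = ["protein_id\tnative_pos\tresidue\tptm_type\tknown_function\tevidence\tsource"]
    for pos, src in at_sites:
        lines.append(f"AtRGS1\t{pos}\t{at[pos]}\tphosphorylation\t"
                     f"{int(pos in at_known)}\tcurated\t{src}")
    for pos, src in gm_sites:
        lines.append(f"GmRGS2\t{pos}\t{gm[pos]}\tphosphorylation\t"
                     f"{int(pos in gm_known)}\tcurated\t{src}")
    (OUT / "rgs_plant_sites.tsv").write_text(
        "# 14 plant phosphosites; the ambiguous AtRGS1 S435/436 is fixed at 436\n"
        + "\n".join(lines) + "\n"
    )

    lysines = [
        "protein_id\tnative_pos\tresidue\tptm_type\tknown_function\tevidence\tsource",
        "GmRGS2\t410\tK\tubiquitination\t0\tcandidate\tproximity-screen",
        "AtRGS1\t411\tK\tubiquitination\t0\tcandidate\tproximity-screen",
    ]
    (OUT / "synthetic_rgs_crosstalk_lysines.tsv").write_text(
        "# candidate (not observed) ubiquitination lysines for the crosstalk screen\n"
        + "\n".join(lysines) + "\n"
    )

    # --- regions ------------------------------------------------------------
    regions = [
        "name\tscope\tprotein_id\tstart\tend",
        "RGS_domain\tnative\tAtRGS1\t284\t416",
        "RGS_domain\tnative\tGmRGS2\t283\t415",
        "RGS_domain_adjacent\tnative\tAtRGS1\t284\t417",
        "cytoplasmic\tnative\tAtRGS1\t284\t459",
        "cytoplasmic\tnative\tGmRGS2\t260\t459",
        "cytoplasmic_aln\talignment\t-\t284\t460",
    ]
    (OUT / "rgs_regions.tsv").write_text("\n".join(regions) + "\n")

    # --- PTM sub-family alignment (non-plant stand-ins) ---------------------
    span_lo = min(start for _, _, start, _ in MAMMALS)
    span_hi = max(start + length - 1 for _, length, start, _ in MAMMALS)
    site_master_cols = {308, 378, 445, 446, 447, 476, 478}
    mam_rows = []
    for name, length, start, required in MAMMALS:
        chars = []
        for col in range(span_lo, span_hi + 1):
            native = col - start + 1
            if not 1 <= native <= length:
                chars.append("-")
                continue
            if native in required:
                chars.append(required[native])
                continue
            if col in site_master_cols:
                copy_p = 0.9
            elif 324 <= col <= 456:      # RGS-domain core
                copy_p = 0.7
            else:
                copy_p = 0.55
            if rng.random() < copy_p:
                chars.append(ancestor[col])
            else:
                chars.append(AMINO_ACIDS[rng.integers(20)])
        mam_rows.append((name, "".join(chars)))
    with open(OUT / "synthetic_rgs_ptm_subfamily_alignment.fasta", "w") as fh:
        for name, row in mam_rows:
            fh.write(f">{name}\n{row}\n")

    fam_sites = [
        ("hRGS2", 46, "S", 1, "PKG"),
        ("hRGS18", 216, "S", 1, "thrombin-stimulated"),
        ("hRGS18", 218, "S", 1, "thrombin-stimulated"),
        ("hRGS10", 168, "S", 1, "PKA"),
        ("rRGS4", 103, "S", 1, "ERK1/2"),
        ("hRGS5", 166, "S", 1, "PKC"),
        ("hRGS7", 434, "S", 1, "14-3-3-linked"),
        ("hRGS16", 168, "Y", 1, "src"),
    ]
    lines = ["protein_id\tnative_pos\tresidue\tptm_type\tknown_function\tevidence\tsource"]
    for pid, pos, res, kf, src in fam_sites:
        lines.append(f"{pid}\t{pos}\t{res}\tphosphorylation\t{kf}\tcurated\t{src}")
    lines.append("hRGS10\t136\tK\tubiquitination\t0\tcurated\tdb-screen")
    (OUT / "rgs_family_sites.tsv").write_text("\n".join(lines) + "\n")

    # --- structure: AtRGS1 RGS-domain stand-in bound to a partner chain -----
    contact_natives = [363, 364, 365, 366, 405, 406]
    spacing = 3.8
    chain_a_res = []
    for p in range(284, 417):
        x = (p - 284) * spacing
        chain_a_res.append(Residue(p, _AA3[at[p]], [Atom("CA", x, 0.0, 0.0)]))
    chain_b_res = []
    for i in range(1, 41):
        if i <= len(contact_natives):
            partner = contact_natives[i - 1]
            x = (partner - 284) * spacing
            chain_b_res.append(
                Residue(i, _AA3[AMINO_ACIDS[rng.integers(20)]],
                        [Atom("CA", x, 0.0, 3.5)])
            )
        else:
            chain_b_res.append(
                Residue(i, _AA3[AMINO_ACIDS[rng.integers(20)]],
                        [Atom("CA", i * spacing, 60.0, 0.0)])
            )
    write_structure_pair(
        StructureChain("A", chain_a_res),
        StructureChain("B", chain_b_res),
        OUT / "synthetic_rgs_structure.pdb",
    )

    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
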