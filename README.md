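# ptmhotspots

Functional prioritization of post-translational modification (PTM) sites
across a protein family.

Most experimentally observed phosphosites have no known function. When a
family's modification data are pooled onto a multiple sequence alignment,
however, functional sites betray themselves: they sit in columns that are
conserved, repeatedly modified across family members, clustered with other
modifications, adjacent to sites with published functional evidence, and
often at protein–protein interfaces. `ptmhotspots` operationalizes this
idea for any protein family. It is built around the plant 7TM-RGS proteins
(AtRGS1, GmRGS2) — receptor-like regulators of heterotrimeric G-protein
signaling whose phosphorylation by receptor-like kinases (RLKs) and WNK
kinases controls G-protein activation — and ships a complete synthetic RGS
case study, but every stage takes ordinary aligned FASTA / TSV / PDB
inputs.

## The model

PTM records are grouped by alignment column into **modified alignment
positions (MAPs)**: columns harboring at least one observed PTM in any
family member. Each MAP receives a feature vector —

| feature | meaning |
|---|---|
| TRC | total residue conservation (modal residue frequency, non-gap rows) |
| PAC | phospho-acceptor (S/T/Y) conservation |
| membership | non-gap fraction of the column |
| PC | count of distinct observed PTMs at the column |
| CPC | cluster PTM count: PTMs within ±w columns, target included |
| NC / NKC | neighboring MAPs within ±w (target excluded) / those with known-function evidence |
| PPI | residence at a protein–protein interface (heavy atoms ≤ 4 Å) |
| PRC | conservation of residues able to accept the MAP's dominant PTM type |

— and MAPs are ranked by the multiplicative **Integrative Score**

```
IS = CPC · PC · PRC · W1(NKC) · W2(PPI)
```

where the conditional weight factors are inactive (= 1) when their
evidence channel is absent: `W1(NKC) = w1·NKC` when NKC > 0 and `W2 = w2`
when the MAP is interface-resident (defaults w1 = w2 = 2). Scores are
quantile-binned for color-coded projection onto structure via the PDB
B-factor column. Companion analyses quantify fold enrichment of observed
sites in regions over random expectation, `(k/n)/(K/N)` over S/T candidate
positions, compare conservation between phosphosite columns and the
phospho-capable background, and screen for phospho–ubiquitin crosstalk
pairs within ±5 residues.

## Worked example

The packaged RGS fixtures transcribe the curated plant phosphosites
(AtRGS1 S339, S365, T375, T379, S417, S428, S436, S453; GmRGS2 T267, S269,
S277, S405, T428, T437) and the named functional sites of non-plant RGS
proteins (hRGS2-S46, hRGS18-S216/S218, hRGS10-S168, rRGS4-S103, hRGS5-S166,
hRGS7-S434, hRGS16-Y168) onto synthetic stand-in sequences. Merging the
plant profile with the PTM sub-family profile and scoring:

```bash
ptmhotspots run \
  --alignment  <data>/synthetic_plant_rgs_alignment.fasta \
  --ptms       <data>/rgs_plant_sites.tsv \
  --ptms       <data>/synthetic_rgs_crosstalk_lysines.tsv \
  --ptms       <data>/rgs_family_sites.tsv \
  --family-alignment <data>/synthetic_rgs_ptm_subfamily_alignment.fasta \
  --structure  <data>/synthetic_rgs_structure.pdb \
  --chain-a A --chain-b B --chain-member AtRGS1 \
  --out-dir out/
```

(`<data>` = `python -c "from ptmhotspots import datasets; print(datasets.plant_alignment_path().parent)"`.)
The top of the resulting `out/ranks.tsv`:

```
rank  column  IS         bin  PC  CPC  PRC       NKC  PPI  member_ptms
1     434     104.0      5    3   5    0.866667  2    1    GmRGS2:405:phosphorylation,hRGS10:136:ubiquitination,hRGS7:434:phosphorylation
2     433     37.333333  5    1   5    0.933333  2    1    hRGS5:166:phosphorylation
3     466     30.0       5    3   5    1.0       1    0    GmRGS2:437:phosphorylation,hRGS10:168:phosphorylation,hRGS18:218:phosphorylation
4     464     18.333333  5    2   5    0.916667  1    0    AtRGS1:436:phosphorylation,hRGS18:216:phosphorylation
```

The top MAP is the column holding GmRGS2-pS405: it is coincident with a
known-functional site (hRGS7-S434), carries a ubiquitination in its
cluster, and sits at the modeled RGS–Gα interface, so both conditional
weights activate (NKC = 2, PPI = 1). Ranks 3–4 are the C-terminal
"phosphorylation island" where GmRGS2-S437 and AtRGS1-S436 co-align with
functional human sites. `out/crosstalk.tsv` reports the single
phospho–ubiquitin pair `GmRGS2 405–410 (distance 5)`, and
`out/enrichment.tsv` gives the AtRGS1 RGS-domain enrichment
`k=5, n=8, K=13, N=29 → fold 1.394`. `out/projected.pdb` holds the score
bins in the B-factor column for molecular-viewer coloring.

Synthetic benchmark data for any stage can be generated with
`ptmhotspots simulate --out-dir sim/`.

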