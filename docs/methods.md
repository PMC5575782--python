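# Methods

## Modified alignment positions

All coordinates are 1-based; intervals are inclusive at both ends. A PTM
record names a protein, a native (ungapped) position, the residue letter,
a modification type and a known-function flag; records are validated
against the alignment on input (the claimed residue must equal the
sequence letter at that position) and exact duplicates collapse to one
record with the known-function flags OR-ed — an observation is
site-level, functionality is evidence-level, so one positive report
suffices. Records are grouped into MAPs by the alignment column their
residue occupies, via a per-row bijection between ungapped positions and
non-gap columns.

## Features

Conservation features (TRC, PAC, PRC) use non-gap rows as the
denominator; gap abundance is reported separately as membership, keeping
the features orthogonal. An all-gap column yields (0, 0, 0) with a
degenerate flag. Conservation can be computed over all rows or only the
focal (query) sub-family — the plant-family analysis uses query rows, the
merged-family analysis all rows.

Cluster statistics around a MAP at column c with half-width w (default
2): CPC sums distinct PTMs over all MAPs with |col − c| ≤ w *including*
the target; NC and NKC count neighboring MAPs (1 ≤ |col − c| ≤ w),
*excluding* the target, so NC ≤ 2w. CPC counts PTMs, not MAPs. Windows
truncate at the alignment bounds.

PRC classifies a column's residues against the acceptor class of the
MAP's dominant modification type (ties resolved toward phosphorylation):
phosphorylation → {S, T, Y}; ubiquitination and acetylation → {K};
methylation → {K, R}; any other type falls back to the set of modified
letters actually observed in the MAP.

Interface residence is true when any interface set (native residue
positions of a named family member) intersects the MAP's column after
translation through that member's residue map.

The crosstalk screen reports all same-protein
(phosphorylation, ubiquitination) record pairs within ±5 native residues,
boundary inclusive.

## Integrative Score, ranking, binning

`IS = CPC · PC · PRC · W1(NKC) · W2(PPI)`. The weight factors are
*conditional multipliers*: a multiplicative score must not vanish when an
optional evidence channel is merely absent, so W1 = 1 when NKC = 0 and
w1·NKC otherwise (a binary mode, W1 = w1 whenever NKC > 0, is available
by configuration; the count mode is the default), and W2 = 1 unless the
MAP is interface-resident, then w2. Defaults w1 = w2 = 2, constrained
≥ 1. PRC enters as a fraction in [0, 1]; using a percentage would scale
every score by 100 without affecting any rank.

Ranking is by descending IS with deterministic tie-breaks: higher CPC,
then higher PC, then lower column index. Binning for structural
projection assigns bin 0 to zero scores and splits positive scores into
n_bins empirical-CDF bins, `bin = ceil(F · n_bins)` where F is the
fraction of positive scores ≤ the score; equal scores therefore always
share a bin and the top scores land in bin n_bins (all-equal positive
scores all land in the top bin). Projection writes the bin into the PDB
B-factor column with two decimals; unscored residues get 0.00.

## Profile-to-profile merge

The focal sub-alignment is merged with the family (PTM) sub-alignment by
a global dynamic program over profile *columns*, so neither input
alignment is disturbed: within each profile the column order is
preserved, no column is split, and deleting the columns that are all-gap
across one profile's rows recovers that profile exactly. The column-pair
objective is the expected substitution score
Σₓ Σ_y f_A(x)·f_B(y)·S(x,y) with frequencies over non-gap letters
(BLOSUM62 by default; any NCBI-format matrix can be supplied). Gaps are
affine: a run of L inserted gap columns costs open + (L−1)·extend, with
defaults −10 / −0.5 — the standard profile-alignment parameterization,
declared explicitly (and overridable) so merges are reproducible. Ties in
the traceback prefer a column match over a gap in the second profile over
a gap in the first, making the merge deterministic. Columns that are
all-gap within their own profile have a zero frequency vector and score 0
against anything.

## Structure handling

Interface detection uses heavy atoms only (crystal structures usually
lack hydrogens) and an inclusive distance cutoff, 4.0 Å by default. The
implementation uses a k-d tree but has exact all-pairs semantics, and is
symmetric, monotone in the cutoff, and invariant under rigid motion.
Chains are mapped to family members by global pairwise alignment of the
chain's one-letter sequence against the member's ungapped sequence (same
matrix and gap defaults as the profile merge), requiring ≥ 0.95 identity
over aligned positions — loose enough for engineered constructs and point
substitutions, strict enough to reject a wrong family member. Unmodeled
residues simply drop out of the mapping.

## Enrichment and conservation comparison

Enrichment of observed sites in a region is the observed/expected ratio
fold = (k/n)/(K/N) over a candidate set of phospho-capable positions
(S and T by default, Y by option, matching the residue types actually
observed). Candidates and sites are counted on one designated protein's
native coordinates, so the surrounding alignment size is irrelevant; a
region equal to the whole scope folds to exactly 1. Degenerate
denominators (K = 0 or n = 0) yield a flagged undefined result, not an
exception. The packaged AtRGS1 fixture reproduces the counting
k = 5, n = 8, K = 13, N = 29 → fold ≈ 1.39 for the RGS domain plus its
immediately adjacent site.

The conservation comparison contrasts mean TRC and PAC over phosphosite
columns against the background of all other columns (optionally within an
alignment-scope region) carrying at least one S/T/Y among the scope rows;
an explicitly supplied background must be disjoint from the site set.

## Synthetic data

The generator samples a star phylogeny: an ancestor drawn from the
residue background (uniform over the 20 amino acids by default,
configurable) and descendants copying each ancestral letter with
per-column probability c_j, otherwise redrawing; contiguous gap segments
(geometric length, mean 3) are masked in at a per-column start rate. A
star tree is sufficient because every feature under test depends only on
column composition; phylogenetic covariance, realistic indel processes
and compositional biases of real families are deliberately out of scope,
so green tests demonstrate correctness of the statistics, not realism of
the evolutionary model.

Hotspot planting forces selected, well-separated columns (margin
> 2·window + 2) to ≥ 95% acceptor content and places
max(1, Poisson(λ)) phosphorylation records on distinct rows (λ = 6 by
default). A functional_fraction of hotspots (default 0.4, i.e. 2 of 5)
model sites with functional evidence in the family: their records carry
the known-function flag, one extra coincident known-functional record
joins the column (a site observed in another family member at the same
position), the column is marked interface-resident, and two flanking
reference MAPs at ±window carry max(1, Poisson(λ/2)) known-functional
records — together emulating the dense functional clusters (≈ 12 total
PTMs) in which curated family sites concentrate, versus ≈ 6 for a
non-functional hotspot. Background columns receive exactly one record and
lie > 2·window from every hotspot. Ground truth (hotspot, functional,
reference, background columns and interface residues) is returned for
recovery tests.

The default recovery benchmark (40 sequences × 300 columns, baseline
conservation 0.6, gap rate 0.05, 5 hotspots, 30 background singletons,
window 2, default weights) was sized to run in about one second per 100
seeded replicates. Under these conditions all five planted hotspots rank
in the top 10 by IS in ≈ 97% of runs and the two functional hotspots
hold ranks 1–2 in ≈ 97% — imperfect recovery is expected, since a
Poisson(6) hotspot occasionally draws one or two records and becomes
indistinguishable from background.

Synthetic structure pairs place single Cα residues on a widely spaced
line; planted contact pairs sit at Uniform(2.5 Å, cutoff) while every
other inter-chain pair is ≥ cutoff + 2 Å, so interface detection must
recover the planted set exactly.

## Packaged fixtures

The RGS fixtures transcribe curated native site positions onto synthetic
stand-in sequences (file names carry a `synthetic_` prefix wherever the
content stands in for a real reference object). The AtRGS1 stand-in is
built with exactly 29 S/T candidates in its cytoplasmic region (284–459),
13 of them within 284–417, so the enrichment arithmetic over the real
counts is reproduced; the ambiguous AtRGS1 "S435/436" site is fixed at
436. The non-plant stand-ins are windows of a shared master coordinate
frame, so the profile merge places hRGS7-S434 coincident with GmRGS2-S405,
hRGS18-S216 with AtRGS1-S436, and hRGS18-S218/hRGS10-S168 with
GmRGS2-S437, with rRGS4-S103, hRGS5-S166, hRGS16-Y168 and hRGS2-S46 one
to two columns from their plant partners. The synthetic complex plants a
contact patch covering AtRGS1 363–366 and 405–406 at 3.5 Å from the
partner chain. Candidate crosstalk lysines (GmRGS2-K410, AtRGS1-K411)
ship in a separate table from the 14 observed phosphosites because they
are annotations, not observations.

## Numerical and degenerate-input conventions

Validation failures raise a dedicated error hierarchy (alignment shape,
provenance, generic validation) that the CLI maps to exit code 2 (3 for
missing files). Empty PTM tables produce empty, header-only outputs with
a warning rather than an error. All TSV outputs are byte-deterministic
for fixed inputs and seed; floats in tables are rounded to six decimals.
Region intervals are validated against ungapped protein lengths at read
time. Unknown modification types map to `other` rather than erroring,
since site databases carry dozens of types.
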