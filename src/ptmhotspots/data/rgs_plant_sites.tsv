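# 14 plant phosphosites; the ambiguous AtRGS1 S435/436 is fixed at 436
protein_id	native_pos	residue	ptm_type	known_function	evidence	source
AtRGS1	339	S	phosphorylation	0	curated	BRL3
AtRGS1	365	S	phosphorylation	0	curated	BRL3;PEPR1
AtRGS1	375	T	phosphorylation	0	curated	PEPR1
AtRGS1	379	T	phosphorylation	0	curated	PEPR1
AtRGS1	417	S	phosphorylation	0	curated	BAK1
AtRGS1	428	S	phosphorylation	1	curated	BAK1;BRL3;PEPR1;WNK8
AtRGS1	436	S	phosphorylation	1	curated	WNK8
AtRGS1	453	S	phosphorylation	0	curated	BRL3
GmRGS2	267	T	phosphorylation	1	curated	NFR1
GmRGS2	269	S	phosphorylation	0	curated	NFR1
GmRGS2	277	S	phosphorylation	0	curated	NFR1
GmRGS2	405	S	phosphorylation	0	curated	NFR1
GmRGS2	428	T	phosphorylation	0	curated	NFR1
GmRGS2	437	T	phosphorylation	1	curated	NFR1
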