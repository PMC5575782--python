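protein_id	native_pos	residue	ptm_type	known_function	evidence	source
hRGS2	46	S	phosphorylation	1	curated	PKG
hRGS18	216	S	phosphorylation	1	curated	thrombin-stimulated
hRGS18	218	S	phosphorylation	1	curated	thrombin-stimulated
hRGS10	168	S	phosphorylation	1	curated	PKA
rRGS4	103	S	phosphorylation	1	curated	ERK1/2
hRGS5	166	S	phosphorylation	1	curated	PKC
hRGS7	434	S	phosphorylation	1	curated	14-3-3-linked
hRGS16	168	Y	phosphorylation	1	curated	src
hRGS10	136	K	ubiquitination	0	curated	db-screen
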