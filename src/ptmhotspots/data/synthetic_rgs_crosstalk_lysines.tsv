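# candidate (not observed) ubiquitination lysines for the crosstalk screen
protein_id	native_pos	residue	ptm_type	known_function	evidence	source
GmRGS2	410	K	ubiquitination	0	candidate	proximity-screen
AtRGS1	411	K	ubiquitination	0	candidate	proximity-screen
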