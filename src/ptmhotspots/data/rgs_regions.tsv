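name	scope	protein_id	start	end
RGS_domain	native	AtRGS1	284	416
RGS_domain	native	GmRGS2	283	415
RGS_domain_adjacent	native	AtRGS1	284	417
cytoplasmic	native	AtRGS1	284	459
cytoplasmic	native	GmRGS2	260	459
cytoplasmic_aln	alignment	-	284	460
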