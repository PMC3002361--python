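complex_id	helix_motif	dna_sequence	kd_nM
1A1F	DSNR	GACC	0.019
1A1G	DSNR	GCGT	1.8
1A1I	RADR	GCAC	0.068
1A1J	RADR	GCGT	0.035
1A1K	RADR	GACC	9.3
1A1L	RDER	GCAC	5.6
1AAY	RDER	GCGT	2.7
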