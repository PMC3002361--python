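complex_id	protein_protein_kcal	protein_dna_kcal	dna_dna_kcal	total_kcal	intra_protein_kcal
1A1F	-58.47	-414.60	-734.92	-1207.99	-513.38
1A1G	-64.77	-432.7	-722.54	-1220.01	-390.68
1A1I	-65.75	-433.5	-714.52	-1213.77	-367.53
1A1J	-66.12	-438.35	-726.55	-1231.02	-440.24
1A1K	-61.61	-423.81	-728.83	-1214.25	-137.19
1A1L	-89.11	-501.37	-705.23	-1295.71	-210.41
1AAY	-64.44	-432.67	-726.34	-1223.45	-342.07
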