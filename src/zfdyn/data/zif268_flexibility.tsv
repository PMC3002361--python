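complex_id	protein_rmsf_sum_nm	complex_rmsf_sum_nm
1A1F	7.18	9.49
1A1G	6.05	8.70
1A1I	7.72	9.03
1A1J	7.6	10.1
1A1K	5.87	8.38
1A1L	6.10	7.97
1AAY	6.47	8.68
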