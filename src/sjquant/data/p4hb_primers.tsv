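name	fwd	rvs	target_variant	amplicon_bp
P4HB-02_e5-6_e6-7	TCACCGAGCAGAGTGTGTCTG	GATGAACAGGATCTTGCCCTTG	P4HB-02	89
P4HB-021_e2_e2-4	TATCCCACCATCAAGTTCTTCAG	CGACTCCACGTCACCTGTATATT	P4HB-021	148
P4HB-027_e2-3_e4-5	GAATATACAGCTGCAGAGTCC	CTTCATCAAACTTCTTAAAG	P4HB-027	211
P4HB_canonical_e3	GAGAGGCTGATGACATCGTG	GACTCCACCAAGGACTCTGC	P4HB-001	
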