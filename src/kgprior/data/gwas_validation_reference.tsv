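list_name	p_chance	p_chance_unmerged	n_predicted	n_mapped	n_validated	n_validated_unmerged	validated_genes	gene_set_p
DisGeNet	0.49		176	166	1		ATXN3:6.8e-7	0.44
ALSoD	0.33		327	305	2		SCFD1:5.4e-7;ATXN3:6.8e-7	0.24
Manual	0.060	0.33	45	41	2	1	WNT7A:0.00019;ZFP91-CNTF:0.00091	0.057
ClinVar	0.038		192	170	3		WNT7A:0.00019;SCFD1:5.4e-7;UNC13A:2.9e-6	0.065
Union	0.67		575	534	1		ATXN3:6.8e-7	0.72
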