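gene_id	set	expr_23d	expr_52d
At5g45890	SURG	1	90148
At1g29640	SURG	1	635
At3g44300	SURG	1	309
At5g13080	SURG	1	304
At1g73220	SURG	1	113
At2g29460	SURG	1	99
At5g42800	SURG	1	74
At1g13340	SURG	1	16
At2g10940	SDRG	14116	1
At3g16670	SDRG	2788	1
At5g26000	SDRG	70	1
At3g05730	SDRG	55	1
At5g25460	SDRG	53	1
At3g27690	SDRG	25	1
At3g44990	SDRG	0.4	1
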