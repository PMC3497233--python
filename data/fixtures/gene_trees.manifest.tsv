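gene_000	0
gene_001	1
gene_002	2
gene_003	3
gene_004	4
gene_005	5
gene_006	6
gene_007	7
gene_008	8
gene_009	9
gene_010	10
gene_011	11
gene_012	12
gene_013	13
gene_014	14
gene_015	15
gene_016	16
gene_017	17
gene_018	18
gene_019	19
gene_020	20
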