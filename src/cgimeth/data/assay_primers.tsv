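assay	target	forward	reverse	probe
methylight	GRIA4	GGGTTGGTGTAGGTTTGTT	CTCCCCCCTTACTTTCTCACATACACACAA	AACGCCGCGACCGCCACAC
methylight	VIPR2	TCGGTTTCGAGTAGAGAGAATTGG	AAACAAATACAAACGACCGCAAAA	CCCTTCCGAACGCACACCTAACCC
methylight	Alu	GGTTAGGTATAGTGGTTTATATTTGTAATTTTAGAT	ATTAACTAAACTAATCTTAAACTCCTAACCTCA	CCTACCTTAACCTCCC
expression	GRIA4	TCATGTGGACAACATTGAGACA	ATCATAGAGTCCAAAAATGGCAAA
expression	VIPR2	GTCTCTTGCAACAGGAAGCA	TCTCAGGATGAAGGACAGGAA
expression	SLC6A3	CCATACTGAAAGGTGTGGGCT	AGAAGAGATAGTGCAGCGCC
expression	SPOCK1	AGGTAAAATGCAGCCCTCACA	TTCCCCTTCTTTTGCCTGGG
expression	TFRC	GGCACAGCTCTCCTATTGAAAC	CAAAGTCTCCAGCACTCCAACT
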