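cgi	gene	delta_beta_discovery	auc_discovery	delta_beta_validation	auc_validation
chr2:182321761-182323029	ITGA4	0.37	1.00	0.35	0.96
chr4:156129168-156130209	NPY2R	0.27	1.00	0.3	0.97
chr4:157997166-157997686	GLRB	0.30	1.00	0.36	0.97
chr4:107956555-107957453	DKK2	0.32	0.97	0.33	0.97
chr5:136834016-136835146	SPOCK1	0.29	1.00	0.33	0.98
chr5:140864527-140864748	PCDHGA4	0.35	1.00	0.38	0.97
chr5:1444678-1446648	SLC6A3	0.26	1.00	0.29	0.98
chr5:178016558-178017670	COL23A1	0.29	0.98	0.32	0.96
chr5:159399004-159399928	ADRA1B	0.25	0.97	0.31	0.97
chr6:159589636-159591319	FNDC1	0.33	1.00	0.33	0.97
chr6:73330942-73333109	KCNQ5	0.36	1.00	0.33	0.96
chr7:28448716-28450028	CREB5	0.27	1.00	0.27	0.96
chr7:158936507-158938492	VIPR2	0.33	0.96	0.35	0.96
chr8:97505747-97507607	SDC2	0.29	1.00	0.36	0.96
chr8:75896528-75897116	CRISPLD1	0.21	0.96	0.27	0.97
chr10:15761423-15762101	ITGA8	0.30	0.96	0.35	0.97
chr11:105481126-105481422	GRIA4	0.40	1.00	0.41	0.96
chr11:133938850-133939681	JAM3	0.30	1.00	0.29	0.97
chr12:117798076-117799448	NOS1	0.25	0.97	0.27	0.96
chr13:110958891-110960590	COL4A1	0.33	0.96	0.37	0.98
chr16:23846941-23848102	PRKCB	0.25	0.98	0.34	0.97
chr19:48918115-48918340	GRIN2D	0.33	1.00	0.38	0.96
chr21:28337856-28340237	ADAMTS5	0.29	1.00	0.31	0.99
chr22:33453892-33454505	SYN3	0.28	0.97	0.32	0.97
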