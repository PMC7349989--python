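sample	target	tissue_call	stool_methylight	stool_ddpcr
CRC_2	GRIA4	hypermethylated	methylated	methylated
CRC_3	GRIA4	hypermethylated	methylated	methylated
CRC_8	GRIA4	undetectable_methylation	undetectable_methylation	methylated
CRC_12	GRIA4	undetectable_methylation	undetectable_methylation	methylated
CRC_14	GRIA4	not_differentially_methylated	undetectable_methylation	methylated
CRC_19	GRIA4	hypermethylated	methylated	methylated
CRC_21	GRIA4	hypermethylated	undetectable_methylation	undetectable_methylation
CRC_29	GRIA4	not_differentially_methylated	methylated	methylated
CRC_33	GRIA4	hypermethylated	undetectable_methylation	methylated
CRC_34	GRIA4	hypermethylated	undetectable_methylation	methylated
CRC_2	VIPR2	hypermethylated	methylated	methylated
CRC_3	VIPR2	hypermethylated	methylated	methylated
CRC_8	VIPR2	undetectable_methylation	methylated	methylated
CRC_12	VIPR2	hypermethylated	undetectable_methylation	methylated
CRC_14	VIPR2	hypermethylated	methylated	methylated
CRC_19	VIPR2	not_differentially_methylated	methylated	methylated
CRC_21	VIPR2	hypermethylated	undetectable_methylation	undetectable_methylation
CRC_29	VIPR2	hypermethylated	methylated	methylated
CRC_33	VIPR2	hypermethylated	methylated	methylated
CRC_34	VIPR2	not_differentially_methylated	undetectable_methylation	methylated
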