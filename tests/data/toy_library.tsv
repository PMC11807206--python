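shrna_id	gene_id	pool	barcode
GX_sh1	GX	1	AAAAAAAA
GY_sh1	GY	1	CCCCCCCC
GZ_sh1	GZ	1	GGGGGGGG
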