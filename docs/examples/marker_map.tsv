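species_id	gene_id
msp_0001	msp_0001_g000
msp_0001	msp_0001_g001
msp_0002	msp_0002_g000
msp_0002	msp_0002_g001
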