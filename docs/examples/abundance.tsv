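species_id	S001V1	S001V2	S002V1	S002V2
msp_0001	120000.5	98000.0	0	15000.2
msp_0002	880000.0	902000.0	1000000	985000.0
msp_0003	0	0	0	0
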