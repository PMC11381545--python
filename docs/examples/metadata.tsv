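sample_id	subject_id	visit_index	group
S001V1	S001	1	
S001V2	S001	2	
S002V1	S002	1	
S002V2	S002	2	
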