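enzyme	reference_id	position	c3_residue	c4_residues
PEPC	REF	780	A	S
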