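category	key	count
conservation	highly_conserved	76
conservation	conserved	22
conservation	poorly_conserved	57
hosted_location	intronic	57
hosted_location	exonic	2
hosted_location	mirtron	1
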