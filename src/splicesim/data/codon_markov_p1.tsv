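base	A	C	T	G
p1	0.24	0.31	0.19	0.25
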