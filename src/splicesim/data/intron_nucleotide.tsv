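base	A	C	T	G
p0	0.29	0.20	0.30	0.21
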