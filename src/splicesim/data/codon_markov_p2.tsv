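x1	A	C	T	G
A	0.21	0.28	0.21	0.30
C	0.27	0.38	0.21	0.14
T	0.12	0.35	0.20	0.33
G	0.29	0.30	0.19	0.22
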