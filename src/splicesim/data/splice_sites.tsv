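donor	acceptor	probability
GT	AG	0.98
GC	AG	0.01
*	*	0.01
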