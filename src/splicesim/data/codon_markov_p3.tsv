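x1x2	A	C	T	G
AA	0.16	0.35	0.13	0.36
AC	0.22	0.49	0.14	0.15
AT	0.02	0.41	0.14	0.43
AG	0.12	0.55	0.20	0.13
CA	0.09	0.22	0.12	0.57
CC	0.26	0.35	0.28	0.11
CT	0.07	0.26	0.12	0.55
CG	0.17	0.37	0.20	0.26
TA	0.01	0.64	0.34	0.01
TC	0.20	0.48	0.20	0.12
TT	0.10	0.48	0.22	0.20
TG	0.05	0.41	0.30	0.24
GA	0.21	0.25	0.18	0.36
GC	0.15	0.55	0.18	0.12
GT	0.08	0.30	0.16	0.46
GG	0.19	0.39	0.13	0.29
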