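"""Bundled example guide trees.

Three species trees (Ensembl Compara topologies and branch lengths)
spanning increasing divergence: primates ("small"), primates plus rodents
("medium"), and amniotes ("large").  Branch lengths are expected
substitutions per codon.
"""

EXAMPLE_TREES = {
    "primates": ("((((bonobo:0.0031, chimpanzee:0.0025):0.0043, "
                 "human:0.0066):0.0018, gorilla:0.0087):0.0084, "
                 "orangutan:0.0173);"),
    "primates_rodents": ("((rabbit:0.1011, (rat:0.0631, mouse:0.0608)"
                         ":0.0522):0.0019, (gorilla:0.0087, human:0.0084)"
                         ":0.0878);"),
    "amniotes": ("(chicken:0.1295, (opossum:0.1165, ((mouse:0.1149, "
                 "human:0.0962):0.0001, cow:0.1136):0.0144):0.0101);"),
}
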