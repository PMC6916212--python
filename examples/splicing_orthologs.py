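"""Splicing-ortholog ground truth and the Rand index.

Simulates a family on the bundled amniote tree, prints the true
splicing-ortholog groups, and scores two baseline clusterings of the
leaf transcripts with the Rand index: one lumping everything into a
single cluster and one of all singletons.  Real clustering methods land
between these extremes.
"""

from splicesim import SimParams, rand_index, simulate
from splicesim.datasets import EXAMPLE_TREES
from splicesim.io import parse_newick

tree = parse_newick(EXAMPLE_TREES["amniotes"])
result = simulate(tree, SimParams(seed=2))

groups = result.ortholog_groups()
truth = {f"{leaf}:{tid}": i
         for i, g in enumerate(groups)
         for leaf, tids in g.items() for tid in tids}
print(f"leaf transcripts: {len(truth)}, true groups: {len(groups)}")
for i, g in enumerate(groups, 1):
    members = [f"{leaf}:{tid}" for leaf in sorted(g) for tid in g[leaf]]
    print(f"  group {i}: {', '.join(members)}")

one_cluster = {t: 0 for t in truth}
singletons = {t: t for t in truth}
print(f"\nRand index, single cluster: {rand_index(one_cluster, truth):.3f}")
print(f"Rand index, all singletons: {rand_index(singletons, truth):.3f}")
print(f"Rand index, ground truth:   {rand_index(truth, truth):.3f}")
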