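"""Score an estimated cDNA alignment against the simulated truth.

Simulates a small family, takes its true cDNA alignment as the
benchmark, and scores a deliberately naive "estimate" (all sequences
left-justified, no gaps inside) with precision / recall / F-score over
aligned nucleotide pairs.  The naive estimate co-aligns many pairs that
are not homologous, so precision and recall fall well below 1.
"""

from splicesim import SimParams, precision_recall_fscore, simulate
from splicesim.io import parse_newick

tree = parse_newick("((human:0.05,mouse:0.09):0.03,chicken:0.15);")
result = simulate(tree, SimParams(seed=4))
_, true_msa = result.true_alignments()

width = max(len(r.replace("-", "")) for r in true_msa.values())
naive = {rid: row.replace("-", "").ljust(width, "-")
         for rid, row in true_msa.items()}

p, r, f = precision_recall_fscore(naive, true_msa)
print(f"cDNA sequences scored: {len(true_msa)}")
print(f"precision = {p:.3f}   (fraction of estimated pairs that are real)")
print(f"recall    = {r:.3f}   (fraction of real pairs recovered)")
print(f"F-score   = {f:.3f}   (harmonic mean)")
print("\nScoring the truth against itself gives the ceiling:")
print("P = R = F =", precision_recall_fscore(true_msa, true_msa))
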