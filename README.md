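# splicesim

Splicing-aware simulation of gene-family sequence evolution.

Benchmarking spliced-sequence analysis methods — spliced aligners,
multiple cDNA aligners, splicing-orthology and transcript-phylogeny
inference — needs datasets where the true evolutionary relationships are
known, and no gold-standard real data exists for alternative splicing.
`splicesim` generates such datasets: given a rooted guide tree, it
simulates a gene family in which not only the sequences but also the
exon-intron structure of each gene and the set of alternative
transcripts it produces evolve along the branches. Every event is
tracked, so the output includes the exact ground truth: the true
multiple alignments of the leaf genes and cDNAs (homology by descent)
and the splicing-ortholog groups of the leaf transcripts.

## Model

Branch lengths *t* of the guide tree are expected **substitutions per
codon**; all other event classes are tied linearly to that rate. On a
branch of length *t*:

- **Structure (EIC) events** — exon loss, gain, duplication. Expected
  count for a gene with *n* exons:
  `λ_x = n · eic_x · k_eic · t`, for x ∈ {el, eg, ed}, with
  `eic_el + eic_eg + eic_ed = 1`. An exon loss deletes the exon segment
  (and every transcript containing it); a gain inserts a freshly
  generated exon inside an existing intron; a duplication makes a tandem
  copy separated by a new intron.
- **Transcript (TC) events** — transcript loss, and creation by random
  isoform selection (`rs`) or by one alternative-splicing event applied
  to an existing transcript: alternative 5'/3' splice-site choice
  (`a5`, `a3`), exon skipping (`es`), mutually exclusive exons (`me`),
  intron retention (`ir`). Expected count for a gene with *n*
  transcripts: `λ_x = n · tc_x · k_tc · t`, with the seven `tc_*`
  frequencies summing to 1.
- **Sequence events** — codon substitutions (empirical-style 61×61
  codon transition matrix; an event always changes the codon) and
  codon-level indels at `k_indel` events per codon per substitution,
  split `ci`/`cd` between insertions and deletions, lengths from a
  truncated power law. Introns evolve the same way at the nucleotide
  level with rates multiplied by `k_intron`; their splice-site
  dinucleotides are frozen.

The root gene is drawn from calibrated empirical laws: exons per cDNA
(mean 9.62), transcripts per gene (1.45), exon length (170.36 nt, a
multiple of 3), intron length (3730.30 nt), splice sites 98% GT-AG / 1%
GC-AG / 1% other, and position-wise codon and intron nucleotide Markov
chains. Default parameters: `k_nbexons=1.5`, `k_eic=k_tc=5`,
`eic_el=0.4, eic_eg=0.5, eic_ed=0.1`, `tc_rs=0.05`,
`tc_a5=tc_a3=tc_me=0.1`, `tc_es=0.2`, `tc_ir=0.05`, `tc_tl=0.4`.

See `docs/methods.md` for assumptions, calibration details and known
limitations.

## Worked example

```python
from splicesim import SimParams, simulate
from splicesim.datasets import EXAMPLE_TREES
from splicesim.io import parse_newick

tree = parse_newick(EXAMPLE_TREES["primates"])
result = simulate(tree, SimParams(seed=1))
```

Running `python examples/simulate_family.py` (which does the above and
prints summaries) gives:

```
leaf        gene_len  exons  transcripts
bonobo         81374     12            1
chimpanzee     81413     12            1
gorilla        80245     12            1
human          81779     13            1
orangutan      81635     11            1

events logged:            7052
true gene MSA:            5 rows x 83019 columns
true cDNA MSA rows:       5
splicing-ortholog groups: 2

  group 1: bonobo:t1, chimpanzee:t1, gorilla:t1, human:t1
  group 2: orangutan:t3
```

Each leaf carries a ~80 kb gene (intron-dominated), 11–13 exons and its
surviving transcripts. The MSA columns are the global homology columns
implied by the event history — stripping gaps from any row returns that
leaf's output sequence exactly. Here four species inherited the root
transcript unchanged (one splicing-ortholog group), while the orangutan
lineage replaced it with a newly created transcript (its own group).

Other entry points, one capability each, live in `examples/`:
`score_alignment.py` (precision/recall/F-score of an estimated MSA
against the truth), `splicing_orthologs.py` (ortholog groups and the
Rand index), `sampler_moments.py` (moment recovery of the generative
laws). A thin CLI wraps the same library:

```sh
splicesim simulate --tree-string "((a:0.05,b:0.04):0.02,c:0.1);" \
    --seed 1 --out family1
splicesim evaluate-msa --true family1/true_cdna_msa.fasta --est my.fasta
splicesim evaluate-clusters --true family1/ortholog_groups.tsv --est my.tsv
```

`simulate` writes `genes.fasta`, `transcripts.fasta`, `exons.gtf`,
`true_gene_msa.fasta`, `true_cdna_msa.fasta`, `ortholog_groups.tsv`,
`events.tsv` and a JSON manifest.

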