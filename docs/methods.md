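# Methods

## Overview

`splicesim` simulates the evolution of one gene family along a rooted
guide tree whose branch lengths are expected substitutions per codon.
Three coupled layers evolve on every branch, in a fixed order: the
exon-intron structure of the gene, the set of alternative transcripts
produced from it, and the nucleotide sequences of its segments. The
simulation is generative and event-explicit: every event is appended to
a log, and every nucleotide carries a global homology-column identifier,
from which the true multiple alignments are assembled afterwards.

## Root synthesis

The maximum number of exons per cDNA, *m*, is drawn from the
exons-per-transcript law; the gene receives `ceil(k_nbexons · m)` exons
(ceiling, so an *m*-exon isoform always exists). Exon lengths are
positive multiples of 3 — the model treats every exon as a whole number
of codons — and exon sequence is emitted codon by codon from a
three-step Markov chain (first-position marginal, second position
conditional on the first, third conditional on the first two). Stop
codons are *not* filtered out: the chain's printed frequencies are
reproduced exactly, and a substitution landing on a stop codon simply
draws a uniform sense codon. Intron sequence comes from a zero-order
nucleotide chain; the terminal dinucleotides are overwritten with a
splice-site pair drawn as 98% GT-AG, 1% GC-AG, 1% any other pair, so
the sampled length is exact.

Root transcripts are created one at a time: by random isoform selection
with probability proportional to `tc_rs`, otherwise by applying one
alternative-splicing event to a uniformly chosen existing transcript
(type proportional to `tc_a5 : tc_a3 : tc_es : tc_me : tc_ir`). The
first transcript is always a random selection (there is nothing to
splice from), which also covers the `tc_rs = 0` configuration. "Random
selection from all isoforms with at most *m* exons" is implemented as a
two-stage draw — an exon count from the truncated exons-per-transcript
law, then a uniform exon subset of that size — which has the same
support as enumerating the exponentially many isoforms.

## Length and count laws

The four empirical laws are summarized by their first two moments:

| law | mean | std | discretization |
|---|---|---|---|
| exons per transcript | 9.62 | 8.54 | round, floor 1 |
| transcripts per gene | 1.45 | 1.08 | round, floor 1 |
| exon length (nt) | 170.36 | 258.86 | nearest multiple of 3, floor 3 |
| intron length (nt) | 3730.30 | 20126.39 | round, floor 20 |

Each is a log-normal (chosen for the heavy right tails these moments
imply — the intron std is 5.4× its mean) discretized as in the table.
Because discretization shifts moments, the underlying (μ, σ) are
recalibrated numerically at construction: the discretized law's exact
moments are computed (by series summation for the count/exon laws, in
closed form for the clipped intron law, where integer rounding shifts
moments by < 0.02% and is ignored) and a two-dimensional root find
matches them to the targets. The calibrated laws reproduce the target
mean and std to well within 2%. Note that for the intron law the
*sample* standard deviation converges extremely slowly (the relative
standard error of the sample std at n = 10⁶ is of order 1 because the
law's kurtosis is ~10⁶), so empirical checks of that law use the exact
moments; sample means converge normally and are checked by sampling.

The minimum intron length of 20 nt leaves both splice-site
dinucleotides plus an evolvable interior.

## Event rates and dynamic length adjustment

All rates are linear in the branch length *t*. With *n* current units
(exons, transcripts, codons or nucleotides) and per-unit frequency
`f·k`, events of one phase are generated as a continuous-time stream:
exponential waiting times at the current total rate `n·f·k`,
accumulated until they exceed *t*. When an event changes *n* the rate
changes with it — this is the dynamic length adjustment, which avoids
under- or over-estimating event counts on segments that grow or shrink.
For phases that do not change *n* (e.g. substitutions) the realized
count is exactly Poisson(`n·f·k·t`).

Phase order per branch is structure → transcript → sequence; within
phases, exon losses precede gains precede duplications, transcript
losses precede creations (per type, in the order rs, a5, a3, es, me,
ir), and within each segment deletions precede insertions precede
substitutions.

## Structure events

- **Exon loss** removes the exon segment plus its upstream intron (the
  downstream one for the first exon) to restore alternation — the model
  does not specify which intron goes; this rule is deterministic and
  minimal. All transcripts containing the exon are lost with it. Guards:
  a gene keeps at least one exon, and if the cascade empties the
  transcript set one random isoform is regenerated (logged), so no leaf
  is degenerate.
- **Exon gain** splits a uniformly chosen intron at a uniform interior
  point (each half keeps ≥ 4 nt: its surviving splice pair plus a
  freshly sampled dinucleotide at the new extremity) and inserts a
  freshly generated exon. Both intron halves get fresh identities; a
  retention of the original intron recorded in some transcript is
  dropped at the next revalidation, since the retained unit no longer
  exists.
- **Exon duplication** copies an exon in tandem with a fresh identity
  and fresh homology columns — at the alignment level a duplication is
  an insertion, the copy is alignable to nothing — separated from the
  original by a newly generated intron.

Gained and duplicated exons start **absent**: they join transcripts only
through later transcript-creation events. Exon status
(absent/alternative/constitutive) is therefore never simulated
directly; it is induced by comparing transcript sets, and the package
exposes `exon_status` to read it off.

## Transcript events

Alternative 5'/3' events shift one exon boundary by `3 · Geometric(0.5)`
nucleotides (sign uniform: extension into the flanking intron or
truncation of the exon), clipped to keep at least one codon of exon, at
least a splice pair of intron, and non-overlapping extensions from the
two sides of one intron. Shifts are multiples of 3 so the reading frame
is preserved; small frame-preserving shifts dominate in real data. An
extension rewrites the dinucleotide at the new boundary inside the
gene's intron sequence with a draw from the splice-site distribution
("a known type of splice site"); the write happens only once the
candidate transcript is accepted.

Exon skipping removes one exon from a template with at least two;
mutually exclusive exons swaps inclusion within a pair of *consecutive*
gene exons of which the template contains exactly one; intron retention
adds an intron flanked by two consecutive template exons, provided the
facing boundary offsets are zero (an offset into a retained intron
would duplicate sequence). Retained introns enter the cDNA verbatim
even though they may disrupt the frame — the model constrains frame
only through exon lengths.

Every creation event — including those at the root — assigns a fresh
lineage identifier; a transcript that crosses a branch unchanged keeps
its lineage. Splicing-ortholog groups are exactly the leaf transcripts
sharing a lineage, i.e. descendants of one ancestral transcript with no
splicing event anywhere on the path. Candidate transcripts identical to
an existing splice form are rejected and resampled (20 attempts, then
the event is skipped with a warning), keeping the set duplicate-free.

After structure and sequence phases each transcript is re-fitted to the
new gene geometry: offsets are shrunk to the nearest feasible multiple
of 3 and stale retained introns dropped; if two transcripts collapse
onto the same splice form the younger one is removed and logged as a
loss.

## Sequence events

Exons evolve in codon space: deletion runs of L codons (L from a
`P(L=k) ∝ k^-1.7`, k ≤ 10 truncated power law — the classic empirical
indel-length shape) at uniform starts, truncated at the segment end and
never below one codon; insertions of freshly generated codons at
uniform junctions; substitutions by a 61×61 row-stochastic codon
transition matrix with zero diagonal (an event always changes the
codon). The packaged matrix is a synthetic empirical-style construction:
target weights are the codon frequencies implied by the packaged codon
chain, multiplied by 4 per transition-type nucleotide change and
discounted ×0.003 per extra nucleotide hit, then row-normalized.

Introns evolve identically at nucleotide level with rates ×`k_intron`,
with two differences: substituted bases are drawn from the intron
composition with the current base excluded and renormalized, and the
four splice-site positions are immutable — no splice-site evolution is
modeled, so freezing those nucleotides is the only consistent
treatment. Rates are computed on the interior length (the frozen
positions accrue no events). Indels never cross segment boundaries;
segments evolve independently, each from its own random substream.

## Homology tracking and the true alignments

Substitutions keep a nucleotide's column id; deletions drop ids from
the descendant only; insertions mint a contiguous block of fresh ids
anchored to the columns flanking the insertion point at event time
(before the right neighbour when one exists, after the left neighbour
at a sequence end). The global column order is linearized by a
depth-first walk of these anchored blocks. Blocks created by different
branches at the same point are mutually unalignable — any consistent
order is a true alignment — and are emitted in creation order, which
equals pre-order over the tree traversal. Rows are leaf genes (gene
MSA) and leaf cDNAs (cDNA MSA); columns absent from every emitted row
are dropped, so no all-gap columns appear, and stripping gaps from a
row reproduces the output sequence exactly. Internal-node sequences
exist only transiently on the traversal stack.

Randomness is derived hierarchically from the single run seed via
`SeedSequence(seed, spawn_key=(node pre-order index, phase, segment
id))`, making runs reproducible and per-segment streams independent of
iteration order.

## Evaluation metrics

Alignment precision = |Pₑ ∩ Pₜ| / |Pₑ|, recall = |Pₑ ∩ Pₜ| / |Pₜ| and
F = 2PR/(P+R), where Pₑ, Pₜ are the sets of aligned residue pairs of
the estimated and true MSAs (per column, per row pair, both non-gap).
Conventions where the definitions are silent: an empty pair set on both
sides scores precision = recall = 1; F = 0 when P + R = 0. The Rand
index is the fraction of item pairs co-clustered in both or separated
in both clusterings, computed exactly from the contingency table; one
item means no pairs and scores 1. Both metrics are character-agnostic.

## What the defaults do and do not emulate

The default configuration reproduces the summary statistics of real
coding genes (segment lengths and counts, base/codon composition,
splice-site usage) and plausible relative event frequencies (exon
skipping commonest, intron retention rarest, structure drifting toward
more exons). It does **not** model codon dependence within exons, motif
or site-specific conservation, rate heterogeneity within a segment,
splice-site sequence evolution, intron loss/gain, exon-status dynamics,
or gene duplication/loss at the tree level — the guide tree is taken as
given. Passing tests therefore certify the bookkeeping (event
mechanics, rates, ground truth) and the calibrated marginals, not
biological realism beyond those marginals.

Two constants have no printed empirical value and are package choices:
`k_indel = 0.1` (a typical indel:substitution ratio) and
`k_intron = 1.5` (introns evolve faster than exons); both are exposed
as parameters, as are the insertion/deletion shares `ci = cd = 0.5`.

## Numerical and testing choices

Printed probability tables carry two-decimal rounding (the
codon-position-1 row sums to 0.99 as printed); rows are renormalized at
load and validated to sum to 1 within 1e-9. Property-test simulations
run with compact genes (exon mean 30 nt, intron mean 60 nt, ~5 exons
per transcript) so hundreds of full simulations fit in seconds; the
invariants they check are size-independent, and the
default-parameter runs on the three bundled species trees (30 families
each) exercise the full-size regime. Statistical tests use three
binomial/Poisson standard deviations around the model value at fixed
seeds; the calibrated-moment contract is 2% relative.
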