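"""Sequence evolution: substitutions and indels on exon and intron segments.

Exons evolve at the codon level: deletions, then insertions, then
substitutions.  Indel events occur at ``k_indel`` per codon per
substitution per codon, split ``ci``/``cd`` between insertions and
deletions, with lengths from the truncated power-law indel model; each
substitution event replaces the codon at a uniform position with a draw
from its codon-matrix row (never the identity).  Deletions and insertions
run as continuous-time processes whose rate tracks the current codon
count (dynamic length adjustment), and an exon never shrinks below one
codon, so its length stays a positive multiple of 3.

Introns evolve the same way at the nucleotide level with rates multiplied
by ``k_intron``, except that the four splice-site positions (first two
and last two nucleotides) are immutable: substitutions and indels only
touch the interior, which also keeps every intron at least 4 nt long.
Substituted intron bases are drawn from the intron composition model with
the current base excluded and the rest renormalized.

Each segment evolves independently of the others; the engine hands every
segment its own seeded random substream so results do not depend on
iteration order.
"""

from __future__ import annotations

from typing import Callable, Optional, Union

import numpy as np

from .context import IdFactory
from .events import EventLog
from .genome import Exon, GeneStructure, Intron
from .ledger import HomologyLedger
from .models import EmpiricalModels
from .params import SimParams
from .transcripts import _event_stream

__all__ = ["expected_indel_count", "evolve_exon_sequence",
           "evolve_intron_sequence", "evolve_gene_sequences"]

RngFactory = Callable[[int], np.random.Generator]


def expected_indel_count(n_units: int, branch_len: float, params: SimParams,
                         is_intron: bool = False) -> float:
    """Expected total indel events: ``k_indel * n * t`` (x ``k_intron``
    inside introns).  Deletions take share ``cd``, insertions ``ci``."""
    if n_units < 0 or branch_len < 0:
        raise ValueError("n_units and branch_len must be >= 0")
    lam = params.k_indel * n_units * branch_len
    return params.k_intron * lam if is_intron else lam


def _anchors(gene: Optional[GeneStructure], seg_index: Optional[int],
             segment, pos: int) -> tuple[Optional[int], Optional[int]]:
    if gene is not None and seg_index is not None:
        return gene.anchors_at(seg_index, pos)
    left = segment.cols[pos - 1] if pos > 0 else None
    right = segment.cols[pos] if pos < len(segment) else None
    return left, right


def evolve_exon_sequence(exon: Exon, branch_len: float, params: SimParams,
                         models: EmpiricalModels, rng: np.random.Generator,
                         ledger: Optional[HomologyLedger] = None,
                         log: Optional[EventLog] = None, node: str = "?",
                         gene: Optional[GeneStructure] = None,
                         seg_index: Optional[int] = None) -> Exon:
    """Evolve one exon in place: deletions, insertions, substitutions."""
    ledger = ledger if ledger is not None else HomologyLedger()
    log = log if log is not None else EventLog()
    if branch_len < 0:
        raise ValueError("branch length must be >= 0")

    def n_codons() -> int:
        return len(exon) // 3

    def fire_deletion() -> None:
        n = n_codons()
        if n <= 1:
            return  # an exon keeps at least one codon
        start = int(rng.integers(n))
        length = min(models.indel_length.sample(rng), n - start, n - 1)
        if length <= 0:
            return
        del exon.seq[3 * start:3 * (start + length)]
        del exon.cols[3 * start:3 * (start + length)]
        log.add(node, "sequence", "codon_del", target=str(exon.id),
                position=start, payload={"codons": length})

    _event_stream(rng, branch_len,
                  lambda: n_codons() * params.cd * params.k_indel,
                  fire_deletion)

    def fire_insertion() -> None:
        n = n_codons()
        point = int(rng.integers(n + 1))
        length = models.indel_length.sample(rng)
        codons = models.codon_chain.generate_codons(length, rng)
        chars = list("".join(codons))
        cols = ledger.new_columns(3 * length)
        left, right = _anchors(gene, seg_index, exon, 3 * point)
        ledger.register_insertion(cols, left, right)
        exon.seq[3 * point:3 * point] = chars
        exon.cols[3 * point:3 * point] = cols
        log.add(node, "sequence", "codon_ins", target=str(exon.id),
                position=point, payload={"codons": length})

    _event_stream(rng, branch_len,
                  lambda: n_codons() * params.ci * params.k_indel,
                  fire_insertion)

    n_sub = rng.poisson(n_codons() * branch_len)
    for _ in range(n_sub):
        p = int(rng.integers(n_codons()))
        old = "".join(exon.seq[3 * p:3 * p + 3])
        new = models.codon_matrix.sample_target(old, rng)
        exon.seq[3 * p:3 * p + 3] = list(new)
        log.add(node, "sequence", "codon_sub", target=str(exon.id),
                position=p, payload={"old": old, "new": new})
    return exon


def evolve_intron_sequence(intron: Intron, branch_len: float,
                           params: SimParams, models: EmpiricalModels,
                           rng: np.random.Generator,
                           ledger: Optional[HomologyLedger] = None,
                           log: Optional[EventLog] = None, node: str = "?",
                           gene: Optional[GeneStructure] = None,
                           seg_index: Optional[int] = None) -> Intron:
    """Evolve one intron in place at the nucleotide level.

    Rates are per interior nucleotide (the four frozen splice-site
    positions accrue no events) scaled by ``k_intron``.
    """
    ledger = ledger if ledger is not None else HomologyLedger()
    log = log if log is not None else EventLog()
    if branch_len < 0:
        raise ValueError("branch length must be >= 0")
    k = params.k_intron

    def interior() -> int:
        return len(intron) - 4

    def fire_deletion() -> None:
        n = interior()
        if n <= 0:
            return
        start = 2 + int(rng.integers(n))
        length = min(models.indel_length.sample(rng),
                     len(intron) - 2 - start)
        if length <= 0:
            return
        del intron.seq[start:start + length]
        del intron.cols[start:start + length]
        log.add(node, "sequence", "nt_del", target=str(intron.id),
                position=start, payload={"nt": length})

    _event_stream(rng, branch_len,
                  lambda: k * interior() * params.cd * params.k_indel,
                  fire_deletion)

    def fire_insertion() -> None:
        point = 2 + int(rng.integers(interior() + 1))
        length = models.indel_length.sample(rng)
        chars = list(models.intron_chain.generate_sequence(length, rng))
        cols = ledger.new_columns(length)
        left, right = _anchors(gene, seg_index, intron, point)
        ledger.register_insertion(cols, left, right)
        intron.seq[point:point] = chars
        intron.cols[point:point] = cols
        log.add(node, "sequence", "nt_ins", target=str(intron.id),
                position=point, payload={"nt": length})

    _event_stream(rng, branch_len,
                  lambda: k * interior() * params.ci * params.k_indel,
                  fire_insertion)

    n_sub = rng.poisson(k * interior() * branch_len) if interior() > 0 else 0
    for _ in range(n_sub):
        p = 2 + int(rng.integers(interior()))
        old = intron.seq[p]
        intron.seq[p] = models.intron_chain.substitute(old, rng)
        log.add(node, "sequence", "nt_sub", target=str(intron.id),
                position=p, payload={"old": old, "new": intron.seq[p]})
    return intron


def evolve_gene_sequences(gene: GeneStructure, branch_len: float,
                          params: SimParams, models: EmpiricalModels,
                          rng: Union[np.random.Generator, RngFactory],
                          ledger: Optional[HomologyLedger] = None,
                          log: Optional[EventLog] = None,
                          node: str = "?") -> GeneStructure:
    """Evolve every segment of a gene independently.

    ``rng`` may be a Generator (segments drawn from one stream in order)
    or a callable mapping a segment id to its own Generator, which makes
    the result invariant to segment iteration order.
    """
    ledger = ledger if ledger is not None else HomologyLedger()
    log = log if log is not None else EventLog()
    factory: RngFactory
    if callable(rng) and not isinstance(rng, np.random.Generator):
        factory = rng
    else:
        factory = lambda seg_id, _r=rng: _r  # noqa: E731
    for i, seg in enumerate(gene.segments):
        seg_rng = factory(seg.id)
        if isinstance(seg, Exon):
            evolve_exon_sequence(seg, branch_len, params, models, seg_rng,
                                 ledger, log, node, gene, i)
        else:
            evolve_intron_sequence(seg, branch_len, params, models, seg_rng,
                                   ledger, log, node, gene, i)
    return gene
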