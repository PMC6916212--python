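"""Ancestral gene and transcript synthesis at the root of the guide tree.

The root gene is assembled segment by segment: the maximum number of exons
per cDNA (``m``) is sampled first, the gene receives
``ceil(k_nbexons * m)`` exons (the ceiling guarantees an ``m``-exon
isoform always exists), and every exon/intron length, splice-site pair and
nucleotide is drawn from the packaged empirical models.  The root
transcript set is then built by random isoform selection and by applying
alternative-splicing events to already-created transcripts, in the
proportions given by the ``tc_*`` frequencies.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .context import IdFactory
from .events import EventLog
from .genome import Exon, GeneStructure, Intron, Transcript, TranscriptSet
from .ledger import HomologyLedger
from .models import EmpiricalModels
from .params import SimParams

__all__ = ["build_root_gene", "sample_random_isoform",
           "build_root_transcripts", "new_exon", "new_intron"]

#: Retries before giving up on producing a novel transcript.
MAX_CREATE_RETRIES = 20


def new_exon(models: EmpiricalModels, rng: np.random.Generator,
             ledger: HomologyLedger, ids: IdFactory,
             birth_node: str) -> Exon:
    """Generate a fresh exon: sampled length (multiple of 3), codon chain."""
    length = models.exon_length.sample(rng)
    codons = models.codon_chain.generate_codons(length // 3, rng)
    seq = "".join(codons)
    return Exon(ids.segment_id(), seq, ledger.new_columns(length),
                birth_node=birth_node)


def new_intron(models: EmpiricalModels, rng: np.random.Generator,
               ledger: HomologyLedger, ids: IdFactory) -> Intron:
    """Generate a fresh intron; terminal dinucleotides are the splice sites.

    The full sampled length is filled from the nucleotide chain first and
    the terminal dinucleotides are then overwritten with the sampled
    donor/acceptor pair, so the length is exact.
    """
    length = models.intron_length.sample(rng)
    seq = list(models.intron_chain.generate_sequence(length, rng))
    donor, acceptor = models.splice_sites.sample(rng)
    seq[0:2] = list(donor)
    seq[-2:] = list(acceptor)
    return Intron(ids.segment_id(), seq, ledger.new_columns(length))


def build_root_gene(params: SimParams, models: EmpiricalModels,
                    rng: np.random.Generator,
                    ledger: Optional[HomologyLedger] = None,
                    ids: Optional[IdFactory] = None) -> GeneStructure:
    """Sample the ancestral gene structure and sequence.

    The gene's columns are registered with the ledger as the base of the
    global homology order.
    """
    ledger = ledger if ledger is not None else HomologyLedger()
    ids = ids if ids is not None else IdFactory()
    m = models.exons_per_transcript.sample(rng)
    n_exons = math.ceil(params.k_nbexons * m)
    segments = []
    for i in range(n_exons):
        if i > 0:
            segments.append(new_intron(models, rng, ledger, ids))
        segments.append(new_exon(models, rng, ledger, ids, birth_node="root"))
    gene = GeneStructure(segments, m_max=m)
    ledger.register_root([c for s in gene.segments for c in s.cols])
    return gene


def sample_random_isoform(gene: GeneStructure, models: EmpiricalModels,
                          rng: np.random.Generator,
                          ids: IdFactory) -> Transcript:
    """Draw a random isoform with at most ``min(m, n_exons)`` exons.

    The exon count is drawn from the exons-per-transcript law truncated to
    the feasible range, then that many exons are chosen uniformly without
    replacement and kept in gene order.  Sampling by (count, uniform
    subset) gives the same support as enumerating all isoforms without the
    exponential blow-up.
    """
    hi = min(gene.m_max, gene.n_exons)
    c = models.exons_per_transcript.truncated_sample(rng, 1, max(hi, 1))
    exon_ids = [e.id for e in gene.exons()]
    chosen = sorted(rng.choice(len(exon_ids), size=c, replace=False))
    return Transcript(
        transcript_id=ids.transcript_id(),
        lineage_id=ids.lineage_id(),
        exon_refs=[exon_ids[i] for i in chosen],
    )


def build_root_transcripts(gene: GeneStructure, params: SimParams,
                           models: EmpiricalModels, rng: np.random.Generator,
                           ids: Optional[IdFactory] = None,
                           log: Optional[EventLog] = None,
                           node: str = "root") -> TranscriptSet:
    """Build the root's alternative-transcript set.

    The set size is drawn from the transcripts-per-gene law.  Each
    transcript is created by random selection with probability
    proportional to ``tc_rs``, or by one alternative-splicing event type
    (proportional to ``tc_a5:tc_a3:tc_es:tc_me:tc_ir``) applied to a
    uniformly chosen existing transcript.  If ``tc_rs`` is zero the first
    transcript is still created by random selection.  Duplicate splice
    forms are rejected and resampled a bounded number of times; if no
    novel form can be produced the set is returned short, with a warning.
    """
    from . import transcripts as tc_module  # cycle: tc events reuse rs

    ids = ids if ids is not None else IdFactory()
    log = log if log is not None else EventLog()
    n_target = models.transcripts_per_gene.sample(rng)
    types = ("rs", "a5", "a3", "es", "me", "ir")
    weights = np.array([getattr(params, f"tc_{t}") for t in types])
    ts = TranscriptSet()
    for k in range(n_target):
        if len(ts) == 0 or weights.sum() == 0:
            event_type = "rs"  # nothing to splice from / all-zero weights
        else:
            event_type = types[rng.choice(len(types), p=weights / weights.sum())]
        created = tc_module.create_transcript(
            ts, gene, event_type, models, rng, log, node=node, ids=ids,
            phase="transcript")
        if created is None and event_type != "rs":
            # fall back to random selection before giving up on this slot
            created = tc_module.create_transcript(
                ts, gene, "rs", models, rng, log, node=node, ids=ids,
                phase="transcript")
        if created is None:
            log.warn(node, "transcript",
                     f"could not produce a novel transcript for slot {k}; "
                     "returning a short root set")
            break
    return ts
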