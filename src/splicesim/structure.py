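"""Exon-intron-structure change (EIC) events along one branch.

Three elementary events act on the gene structure: exon loss (the exon
segment, and one flanking intron to restore alternation, are deleted from
the gene — every transcript containing the exon is lost with it), exon
gain (a fresh exon is inserted inside an existing intron, splitting it),
and exon duplication (a tandem copy separated from the original by a
fresh intron).  The expected number of events of type ``x`` on a branch
of length ``t`` for a gene with ``n`` exons is ``n * eic_x * k_eic * t``.

Phases run in the order loss, gain, duplication, each with its rate
recomputed from the exon count current at that moment.  Gained and
duplicated exons start in the "absent" state: they belong to no
transcript until a later transcript-creation event picks them up.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .context import IdFactory
from .events import EventLog
from .genome import (GeneStructure, Intron, TranscriptSet, clamp_transcript)
from .ledger import HomologyLedger
from .models import EmpiricalModels
from .params import SimParams
from .root import new_exon, new_intron, sample_random_isoform
from .transcripts import _event_stream

__all__ = ["expected_eic_counts", "apply_exon_loss", "apply_exon_gain",
           "apply_exon_duplication", "evolve_structure"]

#: An intron can only host a new exon if both halves keep >= 4 nt.
_MIN_SPLIT_INTRON = 8


def expected_eic_counts(n_exons: int, branch_len: float,
                        params: SimParams) -> tuple[float, float, float]:
    """(expected losses, gains, duplications): ``n * eic_x * k_eic * t``."""
    if n_exons < 0 or branch_len < 0:
        raise ValueError("n_exons and branch_len must be >= 0")
    scale = n_exons * params.k_eic * branch_len
    return (scale * params.eic_el, scale * params.eic_eg,
            scale * params.eic_ed)


def apply_exon_loss(gene: GeneStructure, transcripts: TranscriptSet,
                    exon_id: int, log: EventLog, node: str = "?"
                    ) -> tuple[GeneStructure, TranscriptSet]:
    """Delete an exon segment and cascade the loss to its transcripts.

    Alternation is restored by removing the exon's upstream intron (the
    downstream one for the first exon).  Losing the gene's last exon is
    refused.  Columns of the deleted segments simply stop propagating in
    this lineage; the ledger keeps them for ancestors that had them.
    """
    if gene.n_exons <= 1:
        log.warn(node, "structure", "exon loss skipped: last exon of gene")
        return gene, transcripts
    i = gene.segment_index(exon_id)
    if i % 2 != 0:
        raise KeyError(f"segment {exon_id} is not an exon")
    if i == 0:
        del gene.segments[0:2]  # exon + downstream intron
    else:
        del gene.segments[i - 1:i + 1]  # upstream intron + exon
    log.add(node, "structure", "exon_loss", target=str(exon_id))
    for t in [t for t in transcripts if exon_id in t.exon_refs]:
        transcripts.remove(t)
        log.add(node, "structure", "transcript_loss",
                target=t.transcript_id,
                payload={"lineage": t.lineage_id,
                         "cause": f"exon_loss:{exon_id}"})
    return gene, transcripts


def apply_exon_gain(gene: GeneStructure, models: EmpiricalModels,
                    rng: np.random.Generator, log: EventLog,
                    node: str = "?",
                    ledger: Optional[HomologyLedger] = None,
                    ids: Optional[IdFactory] = None) -> GeneStructure:
    """Insert a fresh exon inside a uniformly chosen intron.

    The intron is split at a uniform interior point (each half keeps at
    least 4 nt: its original splice pair plus the freshly sampled one at
    the new extremity); the new exon goes between the halves and starts
    absent from every transcript.
    """
    ledger = ledger if ledger is not None else HomologyLedger()
    ids = ids if ids is not None else IdFactory()
    host_idxs = [i for i, s in enumerate(gene.segments)
                 if isinstance(s, Intron) and len(s) >= _MIN_SPLIT_INTRON]
    if not host_idxs:
        log.warn(node, "structure",
                 "exon gain skipped: no intron can host a new exon")
        return gene
    idx = host_idxs[rng.integers(len(host_idxs))]
    host = gene.segments[idx]
    p = int(rng.integers(4, len(host) - 3))  # both halves keep >= 4 nt
    left = Intron(ids.segment_id(), host.seq[:p], host.cols[:p])
    right = Intron(ids.segment_id(), host.seq[p:], host.cols[p:])
    # fresh splice sites at the new extremities of the two halves
    d1, a1 = models.splice_sites.sample(rng)
    d2, a2 = models.splice_sites.sample(rng)
    left.seq[-2:] = list(a1)
    right.seq[0:2] = list(d2)
    exon = new_exon(models, rng, ledger, ids, birth_node=node)
    ledger.register_insertion(exon.cols, left.cols[-1], right.cols[0])
    gene.segments[idx:idx + 1] = [left, exon, right]
    log.add(node, "structure", "exon_gain", target=str(exon.id),
            position=p,
            payload={"host_intron": host.id, "length": len(exon)})
    return gene


def apply_exon_duplication(gene: GeneStructure, models: EmpiricalModels,
                           rng: np.random.Generator, log: EventLog,
                           node: str = "?",
                           ledger: Optional[HomologyLedger] = None,
                           ids: Optional[IdFactory] = None) -> GeneStructure:
    """Tandem-duplicate a uniformly chosen exon.

    The copy (fresh identity, fresh homology columns — at the alignment
    level a duplication is an insertion) lands immediately downstream of
    the original, separated by a newly generated intron, and starts
    absent from every transcript.
    """
    ledger = ledger if ledger is not None else HomologyLedger()
    ids = ids if ids is not None else IdFactory()
    exons = gene.exons()
    orig = exons[rng.integers(len(exons))]
    i = gene.segment_index(orig.id)
    intron = new_intron(models, rng, ledger, ids)
    copy_cols = ledger.new_columns(len(orig))
    copy = type(orig)(ids.segment_id(), list(orig.seq), copy_cols,
                      birth_node=node)
    left, right = gene.anchors_at(i, len(orig))
    ledger.register_insertion(intron.cols + copy_cols, left, right)
    gene.segments[i + 1:i + 1] = [intron, copy]
    log.add(node, "structure", "exon_dup", target=str(orig.id),
            payload={"copy": copy.id, "new_intron": intron.id})
    return gene


def _regenerate_if_empty(gene: GeneStructure, ts: TranscriptSet,
                         models: EmpiricalModels, rng: np.random.Generator,
                         log: EventLog, node: str,
                         ids: IdFactory) -> None:
    if len(ts) == 0:
        t = sample_random_isoform(gene, models, rng, ids)
        ts.add(t)
        log.add(node, "structure", "transcript_create_rs",
                target=t.transcript_id,
                payload={"lineage": t.lineage_id,
                         "cause": "exon-loss cascade emptied the set"})


def evolve_structure(gene: GeneStructure, transcripts: TranscriptSet,
                     branch_len: float, params: SimParams,
                     models: EmpiricalModels, rng: np.random.Generator,
                     log: EventLog, node: str = "?",
                     ledger: Optional[HomologyLedger] = None,
                     ids: Optional[IdFactory] = None
                     ) -> tuple[GeneStructure, TranscriptSet]:
    """Apply all EIC events of one branch: losses, gains, duplications."""
    if branch_len < 0:
        raise ValueError("branch length must be >= 0")
    ledger = ledger if ledger is not None else HomologyLedger()
    ids = ids if ids is not None else IdFactory()

    def fire_loss() -> None:
        exons = gene.exons()
        victim = exons[rng.integers(len(exons))]
        apply_exon_loss(gene, transcripts, victim.id, log, node)
        _regenerate_if_empty(gene, transcripts, models, rng, log, node, ids)
        for t in transcripts:
            clamp_transcript(gene, t)

    _event_stream(
        rng, branch_len,
        lambda: (gene.n_exons * params.eic_el * params.k_eic
                 if gene.n_exons > 1 else 0.0),
        fire_loss)

    _event_stream(
        rng, branch_len,
        lambda: gene.n_exons * params.eic_eg * params.k_eic,
        lambda: apply_exon_gain(gene, models, rng, log, node, ledger, ids))

    _event_stream(
        rng, branch_len,
        lambda: gene.n_exons * params.eic_ed * params.k_eic,
        lambda: apply_exon_duplication(gene, models, rng, log, node,
                                       ledger, ids))

    _dedupe(transcripts, log, node)
    return gene, transcripts


def _dedupe(ts: TranscriptSet, log: EventLog, node: str) -> None:
    """Drop younger transcripts whose splice form collapsed onto an
    older one after clamping (keeps the content-uniqueness invariant)."""
    seen: dict = {}
    for t in list(ts):
        key = t.content_key()
        if key in seen:
            ts.remove(t)
            log.add(node, "structure", "transcript_loss",
                    target=t.transcript_id,
                    payload={"lineage": t.lineage_id,
                             "cause": "collapsed duplicate after clamping"})
        else:
            seen[key] = t
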