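"""Transcript-change (TC) events along one branch.

Two elementary event classes act on the transcript set of a gene:
transcript loss, and transcript creation — either by random isoform
selection or by applying one of the five alternative-splicing event types
(alternative 5'/3' splice-site choice, exon skipping, mutually exclusive
exons, intron retention) to an existing template transcript.  The expected
number of events of type ``x`` on a branch of length ``t`` for a gene with
``n`` transcripts is ``n * tc_x * k_tc * t``.

Every creation event starts a fresh splicing-ortholog lineage; a
transcript that crosses a branch unmodified keeps its lineage id.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .context import IdFactory
from .events import EventLog
from .genome import GeneStructure, Transcript, TranscriptSet
from .models import EmpiricalModels
from .params import SimParams

__all__ = ["expected_tc_counts", "apply_transcript_loss",
           "create_transcript", "evolve_transcripts", "exon_status",
           "CREATION_TYPES"]

CREATION_TYPES = ("rs", "a5", "a3", "es", "me", "ir")
MAX_CREATE_RETRIES = 20


def expected_tc_counts(n_transcripts: int, branch_len: float,
                       params: SimParams) -> dict[str, float]:
    """Expected TC event counts per type: ``n * tc_x * k_tc * t``."""
    if n_transcripts < 0 or branch_len < 0:
        raise ValueError("n_transcripts and branch_len must be >= 0")
    scale = n_transcripts * params.k_tc * branch_len
    return {t: scale * getattr(params, f"tc_{t}")
            for t in CREATION_TYPES + ("tl",)}


def apply_transcript_loss(ts: TranscriptSet, rng: np.random.Generator,
                          log: EventLog, node: str = "?") -> TranscriptSet:
    """Remove a uniformly chosen transcript (guarding the last one)."""
    if len(ts) <= 1:
        log.warn(node, "transcript",
                 "transcript loss skipped: would empty the set")
        return ts
    victim = ts.transcripts[rng.integers(len(ts))]
    ts.remove(victim)
    log.add(node, "transcript", "transcript_loss",
            target=victim.transcript_id,
            payload={"lineage": victim.lineage_id})
    return ts


# ---------------------------------------------------------------------------
# Creation mechanics (shared with root synthesis)
# ---------------------------------------------------------------------------

def _geometric_shift(rng: np.random.Generator) -> int:
    """Signed boundary shift: magnitude 3*Geometric(0.5), sign uniform."""
    mag = 3 * int(rng.geometric(0.5))
    return mag if rng.random() < 0.5 else -mag


def _floor3(x: int) -> int:
    return (x // 3) * 3


def _try_boundary_shift(template: Transcript, gene: GeneStructure,
                        side: str, models: EmpiricalModels,
                        rng: np.random.Generator):
    """Alternative 5' (side='a5') or 3' (side='a3') splice-site choice.

    Shifts one exon boundary by a nonzero multiple of 3: a positive shift
    extends the exon into the flanking intron (and writes a fresh
    splice-site dinucleotide at the new boundary inside the gene's intron
    sequence once the candidate is accepted), a negative shift truncates
    the exon.  Returns ``(candidate, commit)`` where ``commit`` applies
    the deferred splice-site write, or None if infeasible.
    """
    cand = template.copy()
    eligible = []
    for eid in cand.exon_refs:
        intr = (gene.upstream_intron(eid) if side == "a5"
                else gene.downstream_intron(eid))
        if intr is None or intr.id in cand.retained_introns:
            continue
        eligible.append(eid)
    if not eligible:
        return None
    eid = eligible[rng.integers(len(eligible))]
    exon = gene.exon_by_id(eid)
    intr = (gene.upstream_intron(eid) if side == "a5"
            else gene.downstream_intron(eid))
    off5, off3 = cand.offset_pair(eid)
    cur = off5 if side == "a5" else off3
    other = off3 if side == "a5" else off5
    # A neighbouring transcript exon may already extend into this intron
    # from the other side; cap so the two extensions cannot overlap
    # (overlap would duplicate homology columns in the cDNA).
    exons = gene.exons()
    order = {e.id: i for i, e in enumerate(exons)}
    opp_ext = 0
    if side == "a5" and order[eid] > 0:
        prev_id = exons[order[eid] - 1].id
        if prev_id in cand.exon_refs:
            opp_ext = max(0, cand.offset_pair(prev_id)[1])
    elif side == "a3" and order[eid] + 1 < len(exons):
        next_id = exons[order[eid] + 1].id
        if next_id in cand.exon_refs:
            opp_ext = max(0, cand.offset_pair(next_id)[0])
    delta = _geometric_shift(rng)
    new = cur + delta
    # clip: extension bounded by the intron (room for a splice pair and
    # the opposite extension), truncation by the exon (keep >= 1 codon
    # net of the other side).
    ext_cap = max(_floor3(len(intr) - 4 - opp_ext), 0)
    trunc_cap = max(_floor3(len(exon) - 3 - max(0, -other)), 0)
    new = min(new, ext_cap)
    new = max(new, -trunc_cap)
    if new == cur:
        return None
    if side == "a5":
        cand.offsets[eid] = [new, off3]
    else:
        cand.offsets[eid] = [off5, new]
    if cand.offsets[eid] == [0, 0]:
        del cand.offsets[eid]

    def commit() -> None:
        if new <= 0:
            return
        # fresh splice-site pair; keep the half facing the new boundary
        donor, acceptor = models.splice_sites.sample(rng)
        if side == "a5":  # new acceptor just upstream of the extension
            p = len(intr) - new - 2
            intr.seq[p:p + 2] = list(acceptor)
        else:  # new donor just downstream of the extension
            intr.seq[new:new + 2] = list(donor)

    return cand, commit


def _try_exon_skipping(template: Transcript, gene: GeneStructure,
                       rng: np.random.Generator) -> Optional[Transcript]:
    if len(template.exon_refs) < 2:
        return None
    cand = template.copy()
    eid = cand.exon_refs[rng.integers(len(cand.exon_refs))]
    cand.exon_refs.remove(eid)
    cand.offsets.pop(eid, None)
    _drop_invalid_retained(cand, gene)
    return cand


def _try_mutually_exclusive(template: Transcript, gene: GeneStructure,
                            rng: np.random.Generator) -> Optional[Transcript]:
    """Swap inclusion within a consecutive gene-exon pair.

    Eligible pairs are consecutive exons of the *gene* of which the
    template contains exactly one; the contained exon is replaced by its
    neighbour.
    """
    exons = gene.exons()
    present = set(template.exon_refs)
    pairs = []
    for a, b in zip(exons, exons[1:]):
        if (a.id in present) != (b.id in present):
            pairs.append((a.id, b.id))
    if not pairs:
        return None
    a, b = pairs[rng.integers(len(pairs))]
    old, new = (a, b) if a in present else (b, a)
    cand = template.copy()
    order = {e.id: i for i, e in enumerate(exons)}
    refs = [e for e in cand.exon_refs if e != old] + [new]
    cand.exon_refs = sorted(refs, key=order.__getitem__)
    cand.offsets.pop(old, None)
    _drop_invalid_retained(cand, gene)
    return cand


def _try_intron_retention(template: Transcript, gene: GeneStructure,
                          rng: np.random.Generator) -> Optional[Transcript]:
    """Retain an intron lying between two consecutive transcript exons.

    Only introns whose two flanking gene exons are consecutive in the
    template, are not already retained, and face zero boundary offsets are
    eligible (offsets into a retained intron would double-count sequence).
    """
    cand = template.copy()
    order = {e.id: i for i, e in enumerate(gene.exons())}
    eligible = []
    for left, right in zip(cand.exon_refs, cand.exon_refs[1:]):
        if order[right] - order[left] != 1:
            continue
        intr = gene.downstream_intron(left)
        if intr is None or intr.id in cand.retained_introns:
            continue
        if cand.offset_pair(left)[1] != 0 or cand.offset_pair(right)[0] != 0:
            continue
        eligible.append(intr.id)
    if not eligible:
        return None
    cand.retained_introns.add(eligible[rng.integers(len(eligible))])
    return cand


def _drop_invalid_retained(t: Transcript, gene: GeneStructure) -> None:
    order = {e.id: i for i, e in enumerate(gene.exons())}
    pos = {e: i for i, e in enumerate(t.exon_refs)}
    keep = set()
    for iid in t.retained_introns:
        gi = gene.segment_index(iid)
        left, right = gene.segments[gi - 1].id, gene.segments[gi + 1].id
        if left in pos and right in pos and pos[right] - pos[left] == 1 \
                and order[right] - order[left] == 1:
            keep.add(iid)
    t.retained_introns = keep


def create_transcript(ts: TranscriptSet, gene: GeneStructure,
                      event_type: str, models: EmpiricalModels,
                      rng: np.random.Generator, log: EventLog,
                      node: str = "?", ids: Optional[IdFactory] = None,
                      phase: str = "transcript") -> Optional[Transcript]:
    """Add one newly created transcript (fresh lineage) to the set.

    For alternative-splicing types the template is drawn uniformly from
    the current set on each attempt.  Candidates identical to an existing
    splice form are rejected and resampled up to ``MAX_CREATE_RETRIES``
    times; an infeasible event is skipped with a warning.
    """
    if event_type not in CREATION_TYPES:
        raise ValueError(f"unknown creation type {event_type!r}")
    if event_type != "rs" and len(ts) == 0:
        raise ValueError("alternative-splicing creation needs a template")
    ids = ids if ids is not None else IdFactory()
    from .root import sample_random_isoform

    existing = ts.content_keys()
    for _ in range(MAX_CREATE_RETRIES):
        commit = None
        if event_type == "rs":
            cand = sample_random_isoform(gene, models, rng, ids)
            template_id = None
        else:
            template = ts.transcripts[rng.integers(len(ts))]
            template_id = template.transcript_id
            if event_type in ("a5", "a3"):
                shifted = _try_boundary_shift(template, gene, event_type,
                                              models, rng)
                cand = None if shifted is None else shifted[0]
                commit = None if shifted is None else shifted[1]
            elif event_type == "es":
                cand = _try_exon_skipping(template, gene, rng)
            elif event_type == "me":
                cand = _try_mutually_exclusive(template, gene, rng)
            else:
                cand = _try_intron_retention(template, gene, rng)
            if cand is not None:
                cand.transcript_id = ids.transcript_id()
                cand.lineage_id = ids.lineage_id()
        if cand is None:
            continue
        if cand.content_key() in existing:
            continue
        if commit is not None:
            commit()
        ts.add(cand)
        payload = {"lineage": cand.lineage_id}
        if template_id is not None:
            payload["template"] = template_id
        if cand.retained_introns:
            payload["retained_introns"] = ",".join(
                str(i) for i in sorted(cand.retained_introns))
        log.add(node, phase, f"transcript_create_{event_type}",
                target=cand.transcript_id, payload=payload)
        return cand
    log.warn(node, phase,
             f"transcript creation ({event_type}) infeasible after "
             f"{MAX_CREATE_RETRIES} attempts")
    return None


# ---------------------------------------------------------------------------
# Branch driver
# ---------------------------------------------------------------------------

def _event_stream(rng: np.random.Generator, branch_len: float, rate_fn,
                  fire) -> None:
    """Run one event phase as a continuous-time process over the branch.

    Waiting times are exponential at the current total rate (per unit
    branch length), so expected counts track the instantaneous set size —
    the dynamic-adjustment rule.  For a constant-rate phase the realized
    count is exactly Poisson(rate * branch_len).
    """
    tau = 0.0
    while True:
        rate = rate_fn()
        if rate <= 0.0 or branch_len <= 0.0:
            return
        tau += rng.exponential(1.0 / rate)
        if tau > branch_len:
            return
        fire()


def evolve_transcripts(ts: TranscriptSet, gene: GeneStructure,
                       branch_len: float, params: SimParams,
                       models: EmpiricalModels, rng: np.random.Generator,
                       log: EventLog, node: str = "?",
                       ids: Optional[IdFactory] = None) -> TranscriptSet:
    """Apply all TC events of one branch: losses first, then creations.

    Creation phases run per type in the fixed order rs, a5, a3, es, me,
    ir, each with its rate recomputed from the current transcript count.
    """
    if branch_len < 0:
        raise ValueError("branch length must be >= 0")
    ids = ids if ids is not None else IdFactory()

    def loss_rate():
        # with one transcript left, losses are guarded no-ops
        return len(ts) * params.tc_tl * params.k_tc if len(ts) > 1 else 0.0

    _event_stream(rng, branch_len, loss_rate,
                  lambda: apply_transcript_loss(ts, rng, log, node))

    for etype in CREATION_TYPES:
        freq = getattr(params, f"tc_{etype}")

        def creation_rate(freq=freq):
            return len(ts) * freq * params.k_tc

        _event_stream(
            rng, branch_len, creation_rate,
            lambda et=etype: create_transcript(
                ts, gene, et, models, rng, log, node, ids))
    return ts


def exon_status(gene: GeneStructure,
                ts: TranscriptSet) -> dict[int, str]:
    """Classify each exon as absent / alternative / constitutive."""
    counts = {e.id: 0 for e in gene.exons()}
    for t in ts:
        for eid in t.exon_refs:
            counts[eid] += 1
    n = len(ts)
    out = {}
    for eid, c in counts.items():
        if c == 0:
            out[eid] = "absent"
        elif c == n:
            out[eid] = "constitutive"
        else:
            out[eid] = "alternative"
    return out
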