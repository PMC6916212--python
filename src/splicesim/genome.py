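"""Gene structure and transcript containers.

A gene is an ordered, strictly alternating list of exon and intron
segments, starting and ending with an exon.  Every nucleotide of every
segment carries a global homology-column identifier (see
:mod:`splicesim.ledger`) so the true multiple alignment can be read off the
simulation afterwards.  Sequences are stored as lists of single characters
to make in-place substitution and indel editing cheap.

A transcript is an ordered selection of the gene's exons, optionally with
frame-preserving 5'/3' boundary adjustments (positive offsets extend into
the flanking intron, negative offsets truncate the exon) and retained
introns.  Its ``lineage_id`` identifies the splicing-ortholog group: it is
inherited unchanged when a transcript is copied along a branch and replaced
by a fresh id whenever a creation event fires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = ["Exon", "Intron", "GeneStructure", "Transcript", "TranscriptSet",
           "build_cdna", "clamp_transcript"]

_VALID_BASES = frozenset("ACTG")


class _Segment:
    __slots__ = ("id", "seq", "cols")

    def __init__(self, seg_id: int, seq: str | list[str], cols: list[int]):
        self.id = seg_id
        self.seq = list(seq)
        self.cols = list(cols)
        if len(self.seq) != len(self.cols):
            raise ValueError("sequence and column lists differ in length")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def sequence(self) -> str:
        return "".join(self.seq)


class Exon(_Segment):
    """Coding segment; length is always a positive multiple of 3."""

    __slots__ = ("birth_node",)
    kind = "exon"

    def __init__(self, seg_id, seq, cols, birth_node: str = "root"):
        super().__init__(seg_id, seq, cols)
        self.birth_node = birth_node
        self.validate()

    def validate(self) -> None:
        if len(self.seq) < 3 or len(self.seq) % 3 != 0:
            raise ValueError(
                f"exon {self.id} length {len(self.seq)} not a positive "
                "multiple of 3")

    def copy(self) -> "Exon":
        return Exon(self.id, self.seq, self.cols, self.birth_node)


class Intron(_Segment):
    """Non-coding segment; first/last two bases are the splice sites."""

    __slots__ = ()
    kind = "intron"

    def __init__(self, seg_id, seq, cols):
        super().__init__(seg_id, seq, cols)
        self.validate()

    def validate(self) -> None:
        if len(self.seq) < 4:
            raise ValueError(f"intron {self.id} shorter than 4 nt")

    @property
    def donor(self) -> str:
        return "".join(self.seq[:2])

    @property
    def acceptor(self) -> str:
        return "".join(self.seq[-2:])

    def copy(self) -> "Intron":
        return Intron(self.id, self.seq, self.cols)


class GeneStructure:
    """Alternating exon/intron segments plus the sampled cap ``m_max``.

    ``m_max`` is the sampled maximum number of exons a cDNA may use (the
    symbol *m* of the root construction); the root gene has
    ``ceil(k_nbexons * m_max)`` exons.
    """

    __slots__ = ("segments", "m_max")

    def __init__(self, segments: list[_Segment], m_max: int):
        self.segments = list(segments)
        self.m_max = int(m_max)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("gene must contain at least one exon")
        for i, seg in enumerate(segs):
            want = Exon if i % 2 == 0 else Intron
            if not isinstance(seg, want):
                raise ValueError(
                    f"segment {i} breaks exon/intron alternation")
        if not isinstance(segs[-1], Exon):
            raise ValueError("gene must end with an exon")

    def exons(self) -> list[Exon]:
        return self.segments[0::2]

    def introns(self) -> list[Intron]:
        return self.segments[1::2]

    @property
    def n_exons(self) -> int:
        return (len(self.segments) + 1) // 2

    @property
    def sequence(self) -> str:
        return "".join(s.sequence for s in self.segments)

    def segment_index(self, seg_id: int) -> int:
        for i, s in enumerate(self.segments):
            if s.id == seg_id:
                return i
        raise KeyError(f"no segment with id {seg_id}")

    def exon_by_id(self, exon_id: int) -> Exon:
        seg = self.segments[self.segment_index(exon_id)]
        if not isinstance(seg, Exon):
            raise KeyError(f"segment {exon_id} is not an exon")
        return seg

    def upstream_intron(self, exon_id: int) -> Optional[Intron]:
        i = self.segment_index(exon_id)
        return self.segments[i - 1] if i > 0 else None

    def downstream_intron(self, exon_id: int) -> Optional[Intron]:
        i = self.segment_index(exon_id)
        return self.segments[i + 1] if i + 1 < len(self.segments) else None

    # -- homology anchors --------------------------------------------------
    def anchors_at(self, seg_index: int, pos: int
                   ) -> tuple[Optional[int], Optional[int]]:
        """(column before, column at/after) an insertion point.

        The insertion point sits before position ``pos`` of segment
        ``seg_index``; anchors look across segment boundaries so a block
        inserted at a segment edge is placed correctly in the gene-wide
        column order.
        """
        right = None
        seg = self.segments[seg_index]
        if pos < len(seg):
            right = seg.cols[pos]
        else:
            for s in self.segments[seg_index + 1:]:
                if len(s):
                    right = s.cols[0]
                    break
        left = None
        if pos > 0:
            left = seg.cols[pos - 1]
        else:
            for s in reversed(self.segments[:seg_index]):
                if len(s):
                    left = s.cols[-1]
                    break
        return left, right

    def copy(self) -> "GeneStructure":
        return GeneStructure([s.copy() for s in self.segments], self.m_max)


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    lineage_id: str
    exon_refs: list[int]
    #: exon_id -> [off5, off3]; positive = extension into the flanking
    #: intron, negative = truncation; always multiples of 3.
    offsets: dict[int, list[int]] = field(default_factory=dict)
    retained_introns: set[int] = field(default_factory=set)

    def offset_pair(self, exon_id: int) -> tuple[int, int]:
        o = self.offsets.get(exon_id)
        return (o[0], o[1]) if o else (0, 0)

    def content_key(self) -> tuple:
        """Identity of the splice form (ignores transcript/lineage ids)."""
        offs = tuple(self.offset_pair(e) for e in self.exon_refs)
        return (tuple(self.exon_refs), offs,
                frozenset(self.retained_introns))

    def copy(self) -> "Transcript":
        return Transcript(
            transcript_id=self.transcript_id,
            lineage_id=self.lineage_id,
            exon_refs=list(self.exon_refs),
            offsets={k: list(v) for k, v in self.offsets.items()},
            retained_introns=set(self.retained_introns),
        )

    def validate(self, gene: GeneStructure) -> None:
        order = {e.id: i for i, e in enumerate(gene.exons())}
        idxs = [order[e] for e in self.exon_refs]
        if not self.exon_refs:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if idxs != sorted(idxs) or len(set(idxs)) != len(idxs):
            raise ValueError(
                f"transcript {self.transcript_id} violates gene exon order")
        for eid in self.exon_refs:
            off5, off3 = self.offset_pair(eid)
            exon = gene.exon_by_id(eid)
            if off5 % 3 or off3 % 3:
                raise ValueError("boundary offsets must be multiples of 3")
            up, down = gene.upstream_intron(eid), gene.downstream_intron(eid)
            if off5 > 0 and (up is None or off5 > len(up) - 4):
                raise ValueError("5' extension exceeds flanking intron")
            if off3 > 0 and (down is None or off3 > len(down) - 4):
                raise ValueError("3' extension exceeds flanking intron")
            trunc = max(0, -off5) + max(0, -off3)
            if trunc > len(exon) - 3:
                raise ValueError("truncations leave less than one codon")
        exon_pos = {e: i for i, e in zip(idxs, self.exon_refs)}
        for left, right in zip(self.exon_refs, self.exon_refs[1:]):
            if exon_pos[right] - exon_pos[left] != 1:
                continue
            intr = gene.downstream_intron(left)
            if intr is None:
                continue
            ext = max(0, self.offset_pair(left)[1]) \
                + max(0, self.offset_pair(right)[0])
            if ext > len(intr) - 4:
                raise ValueError(
                    "opposing extensions overlap inside one intron")
        for iid in self.retained_introns:
            gi = gene.segment_index(iid)
            left, right = gene.segments[gi - 1].id, gene.segments[gi + 1].id
            if left not in exon_pos or right not in exon_pos \
                    or exon_pos[right] - exon_pos[left] != 1:
                raise ValueError(
                    f"retained intron {iid} not flanked by consecutive "
                    "transcript exons")


class TranscriptSet:
    """Ordered set of distinct transcripts of one gene."""

    __slots__ = ("transcripts",)

    def __init__(self, transcripts: list[Transcript] | None = None):
        self.transcripts = list(transcripts or [])

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def content_keys(self) -> set[tuple]:
        return {t.content_key() for t in self.transcripts}

    def has_content(self, t: Transcript) -> bool:
        return t.content_key() in self.content_keys()

    def add(self, t: Transcript) -> None:
        self.transcripts.append(t)

    def remove(self, t: Transcript) -> None:
        self.transcripts.remove(t)

    def copy(self) -> "TranscriptSet":
        return TranscriptSet([t.copy() for t in self.transcripts])

    def validate(self, gene: GeneStructure) -> None:
        if not self.transcripts:
            raise ValueError("transcript set may not be empty")
        keys = [t.content_key() for t in self.transcripts]
        if len(set(keys)) != len(keys):
            raise ValueError("transcript set contains duplicate splice forms")
        for t in self.transcripts:
            t.validate(gene)


# ---------------------------------------------------------------------------
# cDNA assembly and offset maintenance
# ---------------------------------------------------------------------------

def build_cdna(gene: GeneStructure, transcript: Transcript
               ) -> tuple[str, list[int]]:
    """Spliced sequence of a transcript with its homology columns.

    Concatenates the referenced exons in gene order, applying boundary
    adjustments (extensions pull flanking-intron nucleotides into the cDNA;
    truncations drop exon nucleotides) and splicing retained introns in
    verbatim.
    """
    chars: list[str] = []
    cols: list[int] = []
    refs = transcript.exon_refs
    pos_of = {e.id: i for i, e in enumerate(gene.exons())}
    for k, eid in enumerate(refs):
        exon = gene.exon_by_id(eid)
        off5, off3 = transcript.offset_pair(eid)
        if off5 > 0:
            up = gene.upstream_intron(eid)
            chars.extend(up.seq[-off5:])
            cols.extend(up.cols[-off5:])
        start = -off5 if off5 < 0 else 0
        end = len(exon) + off3 if off3 < 0 else len(exon)
        chars.extend(exon.seq[start:end])
        cols.extend(exon.cols[start:end])
        if off3 > 0:
            down = gene.downstream_intron(eid)
            chars.extend(down.seq[:off3])
            cols.extend(down.cols[:off3])
        if k + 1 < len(refs) and pos_of[refs[k + 1]] == pos_of[eid] + 1:
            intr = gene.downstream_intron(eid)
            if intr is not None and intr.id in transcript.retained_introns:
                chars.extend(intr.seq)
                cols.extend(intr.cols)
    return "".join(chars), cols


def _floor3(x: int) -> int:
    return (x // 3) * 3


def clamp_transcript(gene: GeneStructure, transcript: Transcript) -> bool:
    """Re-fit a transcript's adjustments to the current gene geometry.

    Called after structure or sequence evolution may have resized or
    removed segments.  Offsets are shrunk (to the nearest smaller multiple
    of 3) so they respect the flanking-intron and exon-length bounds, and
    retained introns whose flanking exons are no longer present and
    consecutive are dropped.  Returns True if anything changed.
    """
    changed = False
    for eid in transcript.exon_refs:
        off5, off3 = transcript.offset_pair(eid)
        exon = gene.exon_by_id(eid)
        up, down = gene.upstream_intron(eid), gene.downstream_intron(eid)
        n5 = off5
        if off5 > 0:
            cap = _floor3(len(up) - 4) if up is not None else 0
            n5 = min(off5, max(cap, 0))
        n3 = off3
        if off3 > 0:
            cap = _floor3(len(down) - 4) if down is not None else 0
            n3 = min(off3, max(cap, 0))
        # Truncations may not eat the whole exon; shrink 3' first.
        budget = len(exon) - 3
        t5, t3 = max(0, -n5), max(0, -n3)
        if t5 + t3 > budget:
            t3 = min(t3, max(budget - t5, 0))
            t5 = min(t5, max(budget - t3, 0))
            n5 = -_floor3(t5) if n5 < 0 else n5
            n3 = -_floor3(t3) if n3 < 0 else n3
        if (n5, n3) != (off5, off3):
            changed = True
            if n5 == 0 and n3 == 0:
                transcript.offsets.pop(eid, None)
            else:
                transcript.offsets[eid] = [n5, n3]
    # extensions from the two sides of one intron may not overlap
    pos_of = {e.id: i for i, e in enumerate(gene.exons())}
    for left, right in zip(transcript.exon_refs, transcript.exon_refs[1:]):
        if pos_of[right] - pos_of[left] != 1:
            continue
        intr = gene.downstream_intron(left)
        if intr is None:
            continue
        cap = max(len(intr) - 4, 0)
        e3 = max(0, transcript.offset_pair(left)[1])
        e5 = max(0, transcript.offset_pair(right)[0])
        if e3 + e5 > cap:
            changed = True
            new_e5 = _floor3(max(cap - e3, 0))
            new_e3 = _floor3(max(cap - new_e5, 0))
            if e5 > new_e5:
                pair = transcript.offsets.get(right, [0, 0])
                pair[0] = new_e5
                transcript.offsets[right] = pair
            if e3 > new_e3:
                pair = transcript.offsets.get(left, [0, 0])
                pair[1] = new_e3
                transcript.offsets[left] = pair
    for eid in list(transcript.offsets):
        if transcript.offsets[eid] == [0, 0]:
            del transcript.offsets[eid]

    valid_ids = {s.id for s in gene.segments}
    keep: set[int] = set()
    ref_pos = {e: i for i, e in enumerate(transcript.exon_refs)}
    for iid in transcript.retained_introns:
        if iid not in valid_ids:
            changed = True
            continue
        gi = gene.segment_index(iid)
        left = gene.segments[gi - 1].id
        right = gene.segments[gi + 1].id
        if left in ref_pos and right in ref_pos \
                and ref_pos[right] - ref_pos[left] == 1 \
                and pos_of[right] - pos_of[left] == 1:
            keep.add(iid)
        else:
            changed = True
    transcript.retained_introns = keep
    return changed
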