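"""Root-to-leaf simulation driver and ground-truth assembly.

``simulate`` builds the ancestral gene and transcript set at the root of
the guide tree and walks the tree depth-first; on every branch it applies
the three phases in order — structure events, transcript events, sequence
events — so each node inherits everything that happened on the path from
the root.  Branch lengths are expected substitutions per codon.

All randomness is derived hierarchically from the single seed via
``numpy``'s ``SeedSequence`` keyed by (node pre-order index, phase,
segment id), so a run is fully reproducible and per-segment evolution is
independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import sequence as seq_mod
from . import structure as struct_mod
from . import transcripts as tc_mod
from .context import IdFactory
from .events import EventLog, PHASES
from .genome import (GeneStructure, TranscriptSet, build_cdna,
                     clamp_transcript)
from .ledger import HomologyLedger
from .models import EmpiricalModels, build_default_models
from .params import SimParams
from .root import build_root_gene, build_root_transcripts

__all__ = ["TreeNode", "GuideTree", "LeafResult", "SimulationResult",
           "simulate", "collect_ortholog_groups", "build_true_alignments"]


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str
    length: Optional[float]  # None at the root
    children: list["TreeNode"] = field(default_factory=list)
    index: int = -1  # pre-order rank, assigned by GuideTree

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GuideTree:
    """Rooted tree with branch lengths in expected substitutions/codon."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index()
        self.validate()

    def _index(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.index = i

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None or node.length < 0:
                raise ValueError(
                    f"branch to {node.label!r} lacks a non-negative length")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class LeafResult:
    gene: GeneStructure
    transcripts: TranscriptSet
    #: transcript id -> (cDNA sequence, homology columns)
    cdnas: dict[str, tuple[str, list[int]]]


@dataclass
class SimulationResult:
    tree: GuideTree
    params: SimParams
    seed: int
    leaves: dict[str, LeafResult]
    events: EventLog
    ledger: HomologyLedger
    root_gene: GeneStructure
    root_transcripts: TranscriptSet

    def ortholog_groups(self) -> list[dict[str, list[str]]]:
        return collect_ortholog_groups(self)

    def true_alignments(self) -> tuple[dict[str, str], dict[str, str]]:
        return build_true_alignments(self)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_PHASE_CODE = {"root_gene": 0, "root_transcripts": 1, "structure": 2,
               "transcript": 3, "sequence": 4}


def _rng(seed: int, node_index: int, phase: str,
         segment_id: int = 0) -> np.random.Generator:
    key = (node_index, _PHASE_CODE[phase], segment_id)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate(tree: GuideTree, params: SimParams,
             models: Optional[EmpiricalModels] = None,
             seed: Optional[int] = None) -> SimulationResult:
    """Run one full simulation; deterministic for fixed inputs."""
    if not isinstance(tree, GuideTree):
        raise TypeError("tree must be a GuideTree (see io.parse_newick)")
    models = models if models is not None else build_default_models()
    seed = params.seed if seed is None else int(seed)

    ledger = HomologyLedger()
    ids = IdFactory()
    log = EventLog()

    root = tree.root
    gene0 = build_root_gene(params, models,
                            _rng(seed, root.index, "root_gene"),
                            ledger, ids)
    ts0 = build_root_transcripts(gene0, params, models,
                                 _rng(seed, root.index, "root_transcripts"),
                                 ids, log, node=root.label)

    leaves: dict[str, LeafResult] = {}
    stack: list[tuple[TreeNode, GeneStructure, TranscriptSet]] = [
        (root, gene0, ts0)]
    while stack:  # pre-order: branches evolve in traversal order
        node, gene, ts = stack.pop()
        if node is not root:
            gene, ts = gene.copy(), ts.copy()
            _evolve_branch(gene, ts, node, params, models, seed, ledger,
                           ids, log)
        if node.is_leaf:
            cdnas = {t.transcript_id: build_cdna(gene, t) for t in ts}
            leaves[node.label] = LeafResult(gene, ts, cdnas)
        for child in reversed(node.children):
            stack.append((child, gene, ts))

    return SimulationResult(tree=tree, params=params, seed=seed,
                            leaves=leaves, events=log, ledger=ledger,
                            root_gene=gene0, root_transcripts=ts0)


def _evolve_branch(gene: GeneStructure, ts: TranscriptSet, node: TreeNode,
                   params: SimParams, models: EmpiricalModels, seed: int,
                   ledger: HomologyLedger, ids: IdFactory,
                   log: EventLog) -> None:
    t = float(node.length)
    struct_mod.evolve_structure(
        gene, ts, t, params, models, _rng(seed, node.index, "structure"),
        log, node.label, ledger, ids)
    tc_mod.evolve_transcripts(
        ts, gene, t, params, models, _rng(seed, node.index, "transcript"),
        log, node.label, ids)
    seq_mod.evolve_gene_sequences(
        gene, t, params, models,
        lambda seg_id: _rng(seed, node.index, "sequence", seg_id),
        ledger, log, node.label)
    for tr in ts:
        clamp_transcript(gene, tr)
    struct_mod._dedupe(ts, log, node.label)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def collect_ortholog_groups(result: SimulationResult
                            ) -> list[dict[str, list[str]]]:
    """Splicing-ortholog groups: leaf transcripts sharing a lineage id.

    A lineage id survives a branch only if the transcript crossed it with
    no alternative-splicing event, so each group is exactly the set of
    descendants of one ancestral transcript with an event-free history.
    Groups partition the leaf transcripts.
    """
    by_lineage: dict[str, dict[str, list[str]]] = {}
    for leaf, rec in result.leaves.items():
        for t in rec.transcripts:
            by_lineage.setdefault(t.lineage_id, {}).setdefault(
                leaf, []).append(t.transcript_id)
    # deterministic order: by lineage creation number
    return [by_lineage[k] for k in
            sorted(by_lineage, key=lambda s: int(s[1:]))]


def _rows_to_msa(rows: dict[str, tuple[list[str] | str, list[int]]],
                 order: list[int]) -> dict[str, str]:
    used: set[int] = set()
    maps: dict[str, dict[int, str]] = {}
    for rid, (chars, cols) in rows.items():
        m = dict(zip(cols, chars))
        if len(m) != len(cols):
            raise RuntimeError(f"duplicate homology column in row {rid}")
        maps[rid] = m
        used.update(cols)
    columns = [c for c in order if c in used]
    pos = {c: i for i, c in enumerate(columns)}
    msa: dict[str, str] = {}
    for rid, (chars, cols) in rows.items():
        prev = -1
        for c in cols:  # per-row order must embed in the global order
            if pos[c] <= prev:
                raise RuntimeError(
                    f"row {rid} is inconsistent with the global column "
                    "order")
            prev = pos[c]
        row = ["-"] * len(columns)
        for c, ch in zip(cols, chars):
            row[pos[c]] = ch
        msa[rid] = "".join(row)
    return msa


def build_true_alignments(result: SimulationResult
                          ) -> tuple[dict[str, str], dict[str, str]]:
    """True gene MSA (one row per leaf gene) and cDNA MSA.

    Columns are the ledger's global homology columns restricted to those
    present in at least one emitted row; stripping gaps from any row
    reproduces the corresponding output sequence exactly.
    """
    order = result.ledger.linearize()
    gene_rows = {}
    for leaf, rec in result.leaves.items():
        chars = [ch for s in rec.gene.segments for ch in s.seq]
        cols = [c for s in rec.gene.segments for c in s.cols]
        gene_rows[leaf] = (chars, cols)
    cdna_rows = {}
    for leaf, rec in result.leaves.items():
        for tid, (seq, cols) in rec.cdnas.items():
            cdna_rows[f"{leaf}:{tid}"] = (seq, cols)
    return _rows_to_msa(gene_rows, order), _rows_to_msa(cdna_rows, order)
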