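"""Readers and writers: Newick guide trees, FASTA/GTF/TSV outputs, config.

The output bundle of a simulation is plain text throughout: leaf gene
sequences and per-transcript cDNAs as FASTA, exon locations on the gene
as GTF (1-based inclusive coordinates, "+" strand — the simulation is
strandless), the two true multiple alignments as gap-padded multi-FASTA,
splicing-ortholog groups and the event log as TSV, and a JSON manifest
with the parameters and seed of the run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engine import GuideTree, SimulationResult, TreeNode
from .params import SimParams

__all__ = ["parse_newick", "read_tree_file", "write_outputs",
           "load_config", "save_config", "read_fasta", "read_groups_tsv"]


# ---------------------------------------------------------------------------
# Newick input
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> GuideTree:
    """Parse a rooted Newick string with branch lengths into a GuideTree.

    Unnamed internal nodes are labelled deterministically (``n<rank>`` by
    pre-order rank).  Missing branch lengths, duplicate leaf names and
    malformed strings raise ``ValueError``.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"failed to parse Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None and dnode.taxon.label:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        length = dnode.edge.length
        node = TreeNode(label=label,
                        length=None if length is None else float(length))
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge length carries no information here
    counter = [0]

    def autolabel(node: TreeNode) -> None:
        if not node.label:
            node.label = f"n{counter[0]}"
        counter[0] += 1
        for c in node.children:
            autolabel(c)

    autolabel(root)
    return GuideTree(root)


def read_tree_file(path: str | Path) -> GuideTree:
    return parse_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records.items()],
        str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


def _segment_starts(gene) -> dict[int, int]:
    starts, pos = {}, 0
    for seg in gene.segments:
        starts[seg.id] = pos
        pos += len(seg)
    return starts


def _gtf_rows(leaf: str, rec) -> list[str]:
    rows = []
    starts = _segment_starts(rec.gene)
    for t in rec.transcripts:
        tid = f"{leaf}:{t.transcript_id}"
        for eid in t.exon_refs:
            exon = rec.gene.exon_by_id(eid)
            off5, off3 = t.offset_pair(eid)
            s0 = starts[eid] - off5          # 0-based inclusive start
            e0 = starts[eid] + len(exon) + off3  # 0-based exclusive end
            attrs = (f'gene_id "{leaf}"; transcript_id "{tid}"; '
                     f'exon_id "{eid}";')
            rows.append("\t".join([
                leaf, "splicesim", "exon", str(s0 + 1), str(e0), ".",
                "+", ".", attrs]))
        for iid in sorted(t.retained_introns):
            intr = rec.gene.segments[rec.gene.segment_index(iid)]
            s0 = starts[iid]
            attrs = (f'gene_id "{leaf}"; transcript_id "{tid}"; '
                     f'intron_id "{iid}";')
            rows.append("\t".join([
                leaf, "splicesim", "retained_intron", str(s0 + 1),
                str(s0 + len(intr)), ".", "+", ".", attrs]))
    return rows


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  force: bool = False) -> dict[str, Path]:
    """Write the full output bundle of one simulation to a directory.

    Refuses to overwrite an existing non-empty directory unless ``force``
    is set.  Returns the paths written, keyed by a short name.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = {leaf: rec.gene.sequence for leaf, rec in result.leaves.items()}
    paths["genes"] = out / "genes.fasta"
    _write_fasta(paths["genes"], genes)

    cdnas = {f"{leaf}:{tid}": seq
             for leaf, rec in result.leaves.items()
             for tid, (seq, _) in rec.cdnas.items()}
    paths["transcripts"] = out / "transcripts.fasta"
    _write_fasta(paths["transcripts"], cdnas)

    paths["exons"] = out / "exons.gtf"
    with open(paths["exons"], "w") as fh:
        for leaf, rec in result.leaves.items():
            for row in _gtf_rows(leaf, rec):
                fh.write(row + "\n")

    gene_msa, cdna_msa = result.true_alignments()
    paths["gene_msa"] = out / "true_gene_msa.fasta"
    _write_fasta(paths["gene_msa"], gene_msa)
    paths["cdna_msa"] = out / "true_cdna_msa.fasta"
    _write_fasta(paths["cdna_msa"], cdna_msa)

    paths["groups"] = out / "ortholog_groups.tsv"
    with open(paths["groups"], "w") as fh:
        fh.write("group\tmembers\n")
        for i, group in enumerate(result.ortholog_groups(), start=1):
            members = [f"{leaf}:{tid}"
                       for leaf in sorted(group)
                       for tid in group[leaf]]
            fh.write(f"g{i}\t{','.join(members)}\n")

    paths["events"] = out / "events.tsv"
    with open(paths["events"], "w") as fh:
        fh.write("\t".join(result.events.HEADER) + "\n")
        for rec in result.events:
            fh.write("\t".join(rec.as_row()) + "\n")

    paths["manifest"] = out / "manifest.json"
    from . import __version__
    manifest = {
        "package": "splicesim",
        "version": __version__,
        "seed": result.seed,
        "params": result.params.as_dict(),
        "n_leaves": result.tree.n_leaves,
        "leaves": sorted(result.leaves),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Config and clustering files
# ---------------------------------------------------------------------------

def load_config(path: str | Path,
                base: Optional[SimParams] = None) -> SimParams:
    """Read a flat YAML key/value file into SimParams.

    Keys mirror the SimParams fields; unknown keys are rejected.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    valid = set(SimParams.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = base if base is not None else SimParams()
    return base.replace(**data)


def save_config(params: SimParams, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(params.as_dict(), sort_keys=True))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Read a ``group<TAB>member1,member2,...`` file into item -> label."""
    out: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for ln in lines:
        if not ln.strip() or ln.startswith("group\t"):
            continue
        group, members = ln.split("\t", 1)
        for m in members.split(","):
            m = m.strip()
            if m:
                if m in out:
                    raise ValueError(f"item {m!r} appears in two groups")
                out[m] = group
    return out
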