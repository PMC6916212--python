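"""Ground-truth-based evaluation metrics.

Alignment accuracy is scored on aligned residue pairs: precision is the
fraction of residue pairs in the estimated alignment also present in the
true alignment, recall the fraction of true pairs recovered, and the
F-score their harmonic mean.  Clusterings (e.g. inferred ortholog groups
against the true splicing-ortholog groups) are scored with the Rand
index: the fraction of item pairs on which the two clusterings agree —
co-clustered in both or separated in both.  All metrics are
character-agnostic (nucleotide or amino-acid alike).
"""

from __future__ import annotations

from math import comb
from typing import Hashable, Mapping

__all__ = ["alignment_pairs", "precision_recall_fscore", "rand_index"]

ResiduePair = tuple[tuple[str, int], tuple[str, int]]


def _check_msa(msa: Mapping[str, str]) -> None:
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ValueError("ragged MSA: rows have different lengths")


def alignment_pairs(msa: Mapping[str, str]) -> set[ResiduePair]:
    """Aligned residue pairs of an MSA.

    For every column and every pair of rows whose characters in that
    column are both non-gap, emits the unordered pair of their 0-based
    ungapped residue indices.  Pairs are stored with the lexicographically
    smaller sequence id first.
    """
    _check_msa(msa)
    ids = sorted(msa)
    counters = {i: -1 for i in ids}
    pairs: set[ResiduePair] = set()
    width = len(next(iter(msa.values()))) if msa else 0
    for col in range(width):
        present = []
        for i in ids:
            ch = msa[i][col]
            if ch != "-":
                counters[i] += 1
                present.append((i, counters[i]))
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                pairs.add((present[a], present[b]))
    return pairs


def _ungapped(s: str) -> str:
    return s.replace("-", "")


def precision_recall_fscore(est_msa: Mapping[str, str],
                            true_msa: Mapping[str, str]
                            ) -> tuple[float, float, float]:
    """Precision, recall and F-score of an estimated MSA vs the truth.

    Both MSAs must cover the same sequences (same ids, same ungapped
    sequences).  Conventions: an empty pair set on both sides gives
    precision = recall = 1; F = 0 when precision + recall = 0.
    """
    if set(est_msa) != set(true_msa):
        diff = set(est_msa) ^ set(true_msa)
        raise ValueError(f"MSAs cover different sequences: {sorted(diff)}")
    for rid in est_msa:
        if _ungapped(est_msa[rid]) != _ungapped(true_msa[rid]):
            raise ValueError(
                f"sequence {rid!r} differs between the two alignments")
    p_est = alignment_pairs(est_msa)
    p_true = alignment_pairs(true_msa)
    inter = len(p_est & p_true)
    precision = inter / len(p_est) if p_est else 1.0
    recall = inter / len(p_true) if p_true else 1.0
    if precision + recall == 0:
        return precision, recall, 0.0
    f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


def rand_index(est: Mapping[Hashable, Hashable],
               truth: Mapping[Hashable, Hashable]) -> float:
    """Fraction of item pairs on which two clusterings agree.

    Computed from the contingency table, so it is exact and O(n + K^2) in
    the numbers of items and clusters; symmetric in its arguments and
    invariant under cluster relabelling.  With fewer than two items there
    are no pairs and the index is 1 by convention.
    """
    if set(est) != set(truth):
        diff = set(est) ^ set(truth)
        raise ValueError(f"clusterings cover different items: {sorted(diff)}")
    n = len(est)
    if n < 2:
        return 1.0
    cont: dict[tuple, int] = {}
    a: dict = {}
    b: dict = {}
    for item, e_lab in est.items():
        t_lab = truth[item]
        cont[(e_lab, t_lab)] = cont.get((e_lab, t_lab), 0) + 1
        a[e_lab] = a.get(e_lab, 0) + 1
        b[t_lab] = b.get(t_lab, 0) + 1
    total = comb(n, 2)
    same_both = sum(comb(c, 2) for c in cont.values())
    same_est = sum(comb(c, 2) for c in a.values())
    same_true = sum(comb(c, 2) for c in b.values())
    agreements = total + 2 * same_both - same_est - same_true
    return agreements / total
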