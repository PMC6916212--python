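"""Homology bookkeeping for the true multiple alignment.

Every simulated nucleotide carries a global *column id*.  Substitutions
keep the id; a deletion drops ids from the descendant sequence (the column
survives for lineages that still carry it); an insertion mints a fresh
contiguous block of ids and records where the block sits relative to the
columns that flanked the insertion point when the event fired.

The global column order is the partial order generated by all sequences;
it is linearized deterministically: a block anchored *before* column ``r``
is emitted just before ``r``, after any earlier-created block at the same
anchor; a block created at the end of a sequence is anchored *after* its
left neighbour.  Blocks created by different branches at the same point
are mutually unalignable, so any consistent order is a true alignment —
creation order (pre-order over the tree traversal) is the deterministic
tie-break.
"""

from __future__ import annotations

from typing import Optional

__all__ = ["HomologyLedger"]


class HomologyLedger:
    def __init__(self) -> None:
        self._next_col = 0
        self._root: list[int] = []
        # col id -> blocks (lists of column ids) anchored immediately
        # before / after that column, in creation order.
        self._before: dict[int, list[list[int]]] = {}
        self._after: dict[int, list[list[int]]] = {}

    # -- column creation ---------------------------------------------------
    def new_columns(self, n: int) -> list[int]:
        cols = list(range(self._next_col, self._next_col + n))
        self._next_col += n
        return cols

    @property
    def n_columns(self) -> int:
        return self._next_col

    def register_root(self, cols: list[int]) -> None:
        """Declare the root sequence's columns (the base of the order)."""
        if self._root:
            raise RuntimeError("root columns already registered")
        self._root = list(cols)

    def register_insertion(self, cols: list[int],
                           left: Optional[int], right: Optional[int]) -> None:
        """Place a freshly minted block between its creation-time anchors.

        ``right`` wins when present (the block goes immediately before
        it); otherwise the block is appended after ``left``.  At least one
        anchor must exist, because sequences are never empty.
        """
        if not cols:
            return
        if right is not None:
            self._before.setdefault(right, []).append(list(cols))
        elif left is not None:
            self._after.setdefault(left, []).append(list(cols))
        else:
            raise ValueError("insertion block needs at least one anchor")

    # -- linearization -----------------------------------------------------
    def linearize(self) -> list[int]:
        """Deterministic total order over all columns ever created."""
        out: list[int] = []
        # Depth-first over nested anchored blocks with an explicit stack
        # (insertion nesting can exceed the recursion limit in long
        # simulations).  For each column: blocks-before, the column
        # itself, blocks-after.
        work: list[tuple[str, int]] = [
            ("col", c) for c in reversed(self._root)]
        while work:
            kind, col = work.pop()
            if kind == "emit":
                out.append(col)
                continue
            tasks: list[tuple[str, int]] = []
            for blk in self._before.get(col, ()):
                tasks.extend(("col", c) for c in blk)
            tasks.append(("emit", col))
            for blk in self._after.get(col, ()):
                tasks.extend(("col", c) for c in blk)
            work.extend(reversed(tasks))
        if len(out) != self._next_col:
            raise RuntimeError(
                "homology ledger inconsistent: linearization covers "
                f"{len(out)} of {self._next_col} columns")
        return out
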