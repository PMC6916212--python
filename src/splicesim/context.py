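"""Stable identifier factories shared across one simulation."""

from __future__ import annotations

__all__ = ["IdFactory"]


class IdFactory:
    """Mints globally unique segment, transcript and lineage identifiers.

    Segment ids are integers (exons and introns share one counter);
    transcript ids are ``t<n>`` and splicing-ortholog lineage ids ``L<n>``.
    Ids are assigned in creation order, which makes them deterministic for
    a fixed seed.
    """

    def __init__(self) -> None:
        self._seg = 0
        self._tr = 0
        self._lin = 0

    def segment_id(self) -> int:
        self._seg += 1
        return self._seg

    def transcript_id(self) -> str:
        self._tr += 1
        return f"t{self._tr}"

    def lineage_id(self) -> str:
        self._lin += 1
        return f"L{self._lin}"
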