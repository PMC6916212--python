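"""Event records and the per-simulation event log."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

logger = logging.getLogger("splicesim")

__all__ = ["EventRecord", "EventLog", "PHASES", "logger"]

#: Per-branch phase order: structure changes, then transcript changes,
#: then sequence changes.
PHASES = ("structure", "transcript", "sequence")


@dataclass(slots=True)
class EventRecord:
    index: int
    node: str
    phase: str
    type: str
    target: str = ""
    position: Optional[int] = None
    payload: Optional[dict[str, Any]] = None

    def as_row(self) -> list[str]:
        payload = "" if not self.payload else ";".join(
            f"{k}={v}" for k, v in sorted(self.payload.items()))
        pos = "" if self.position is None else str(self.position)
        return [str(self.index), self.node, self.phase, self.type,
                self.target, pos, payload]


class EventLog:
    """Append-only log of every simulated event, in firing order."""

    HEADER = ["index", "node", "phase", "type", "target", "position",
              "payload"]

    def __init__(self) -> None:
        self.records: list[EventRecord] = []

    def add(self, node: str, phase: str, type: str, target: str = "",
            position: Optional[int] = None,
            payload: Optional[dict[str, Any]] = None) -> EventRecord:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        rec = EventRecord(len(self.records), node, phase, type, target,
                          position, payload)
        self.records.append(rec)
        return rec

    def warn(self, node: str, phase: str, message: str) -> None:
        logger.warning("%s [%s]: %s", node, phase, message)
        self.add(node, phase, "skipped_event", payload={"reason": message})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
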