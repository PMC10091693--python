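"""The event x sample MCF matrix — the pipeline's central intermediate.

Each row is one copy-number alteration matched across samples; each entry
is the mutated cell fraction (MCF) of that alteration in that sample.
Missing observations are NaN; an event *absent* in a sample is 0.0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CNAEvent, GenomicSegment

__all__ = ["EventMatrix", "event_row_label", "parse_row_label"]


def event_row_label(event: CNAEvent) -> str:
    """Row id ``chrom:start-end:kind`` (1-based inclusive); ``wgd`` alone
    for the genome-wide event."""
    if event.kind == "wgd":
        return "wgd"
    seg = event.segment
    assert seg is not None
    return f"{seg.chrom}:{seg.start + 1}-{seg.end}:{event.kind}"


_LABEL_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<kind>\w+)$")


def parse_row_label(label: str, event_id: str | None = None) -> CNAEvent:
    """Inverse of :func:`event_row_label` (coordinates back to 0-based)."""
    if label.strip().lower() == "wgd":
        return CNAEvent(event_id or "wgd", "wgd")
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"unparseable event row label {label!r}")
    kind = m["kind"]
    delta = {"gain": 1, "loss": -1}.get(kind, 0)
    seg = GenomicSegment(m["chrom"], int(m["start"]) - 1, int(m["end"]))
    return CNAEvent(event_id or label, kind, seg, delta)


@dataclass
class EventMatrix:
    """Events x samples MCF matrix.

    ``mcf[i, j]`` is the MCF of ``events[i]`` in ``samples[j]``, in [0, 1].
    NaN encodes a missing observation (allowed); absence is explicit 0.0.
    """

    events: list[CNAEvent]
    samples: list[str]
    mcf: np.ndarray

    def __post_init__(self) -> None:
        self.mcf = np.asarray(self.mcf, dtype=float)
        if self.mcf.shape != (len(self.events), len(self.samples)):
            raise ValueError(
                f"mcf shape {self.mcf.shape} inconsistent with "
                f"{len(self.events)} events x {len(self.samples)} samples"
            )
        finite = self.mcf[np.isfinite(self.mcf)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("MCF values must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def row_labels(self) -> list[str]:
        return [event_row_label(e) for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mcf, index=self.row_labels, columns=self.samples)

    def profile(self, event_id: str) -> np.ndarray:
        for i, ev in enumerate(self.events):
            if ev.event_id == event_id:
                return self.mcf[i]
        raise KeyError(event_id)

    def subset(self, keep: list[int]) -> "EventMatrix":
        return EventMatrix(
            [self.events[i] for i in keep], list(self.samples), self.mcf[keep]
        )

    def without_kinds(self, kinds: tuple[str, ...] = ("complex",)) -> "EventMatrix":
        keep = [i for i, e in enumerate(self.events) if e.kind not in kinds]
        return self.subset(keep)
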