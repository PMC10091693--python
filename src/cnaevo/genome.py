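"""Coordinate system, segments, and copy-number event algebra.

Everything downstream (simulation, array emulation, calling, phylogeny)
shares these types.  Internal coordinates are 0-based half-open; every TSV
on disk is 1-based inclusive (SNP-array convention) and the shift happens
only in :mod:`cnaevo.fileio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomeBuild",
    "GenomicSegment",
    "CNAEvent",
    "EVENT_KINDS",
    "event_length",
    "size_filter",
    "reciprocal_overlap",
    "DEFAULT_MIN_EVENT_LEN",
]

#: Inclusive size threshold (bp) for "large" chromosomal aberrations.
DEFAULT_MIN_EVENT_LEN = 1_000_000

EVENT_KINDS = ("gain", "loss", "cnloh", "wgd", "complex")

# Approximate human chromosome lengths in Mbp (GRCh38 scale, rounded).
_HUMAN_MBP = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51, "chrX": 156, "chrY": 57,
}


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @classmethod
    def default(cls) -> "GenomeBuild":
        """24-chromosome build with approximate human Mbp lengths."""
        return cls(tuple((n, mbp * 1_000_000) for n, mbp in _HUMAN_MBP.items()))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeBuild":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """Half-open interval [start, end) on one chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid segment {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicSegment") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersection(self, other: "GenomicSegment") -> "GenomicSegment":
        if self.overlap_bp(other) == 0:
            raise ValueError("segments do not overlap")
        return GenomicSegment(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class CNAEvent:
    """One copy-number alteration, matched as a unit across samples.

    ``kind`` is one of gain / loss / cnloh / wgd / complex.  ``copy_delta``
    is the per-haplotype copy change: >= 1 for gains, <= -1 for losses, 0
    for cn-LOH (one haplotype lost, the other duplicated).  Whole-genome
    duplication carries no segment — it is a single genome-wide event, not
    24 per-chromosome gains.  ``complex`` events carry a segment but are
    excluded from tree placement (annotated, not decomposed).
    """

    event_id: str
    kind: str
    segment: GenomicSegment | None = None
    copy_delta: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "wgd":
            if self.segment is not None:
                raise ValueError("wgd is genome-wide and carries no segment")
        elif self.segment is None:
            raise ValueError(f"{self.kind} event requires a segment")
        if self.kind == "gain" and self.copy_delta < 1:
            raise ValueError("gain requires copy_delta >= 1")
        if self.kind == "loss" and self.copy_delta > -1:
            raise ValueError("loss requires copy_delta <= -1")
        if self.kind == "cnloh" and self.copy_delta != 0:
            raise ValueError("cnloh is copy-neutral (copy_delta 0)")


def event_length(event: CNAEvent) -> int:
    """Length in bp of the event's segment.

    Raises ``ValueError`` for genome-wide events (wgd), which have no
    segment.
    """
    if event.segment is None:
        raise ValueError(f"event {event.event_id!r} ({event.kind}) has no segment")
    return event.segment.length


def size_filter(
    events: Sequence[CNAEvent], min_len: int = DEFAULT_MIN_EVENT_LEN
) -> list[CNAEvent]:
    """Keep events with segment length >= ``min_len`` (inclusive).

    Genome-scale events (wgd) are always kept.  Order is preserved and the
    operation is idempotent and monotone in ``min_len``.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = []
    for ev in events:
        if ev.segment is None or ev.segment.length >= min_len:
            kept.append(ev)
    return kept


def reciprocal_overlap(a: GenomicSegment, b: GenomicSegment) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for different chromosomes."""
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)
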