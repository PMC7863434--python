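"""Genomic intervals in the package-wide 0-based, half-open convention.

Every coordinate inside the package is 0-based half-open. SAM input (1-based)
is converted at the boundary by ``vir.io``; BED shares this convention and is
written verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", "unknown")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named reference sequence."""

    ref_name: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.ref_name:
            raise ValueError("ref_name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.ref_name}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", slop: int = 0) -> bool:
        """True if the two intervals overlap when each is widened by ``slop``."""
        if self.ref_name != other.ref_name:
            return False
        return self.start - slop < other.end and other.start - slop < self.end

    def contains_point(self, ref_name: str, pos: int, slop: int = 0) -> bool:
        return self.ref_name == ref_name and self.start - slop <= pos < self.end + slop

    def __str__(self) -> str:  # "ref:start-end" is used as a locus ID string
        return f"{self.ref_name}:{self.start}-{self.end}"


def parse_locus(text: str) -> GenomicInterval:
    """Parse a ``ref:start-end`` locus ID back into an interval."""
    ref, _, span = text.rpartition(":")
    start_s, _, end_s = span.partition("-")
    return GenomicInterval(ref, int(start_s), int(end_s))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= ``gap`` (bedtools ``merge -d`` semantics).

    Intervals on different references never merge. Strand is ignored and the
    merged intervals are reported as strand-unknown, sorted by (ref, start).
    """
    by_ref: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_ref.setdefault(iv.ref_name, []).append(iv)
    merged: list[GenomicInterval] = []
    for ref in sorted(by_ref):
        ivs = sorted(by_ref[ref], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(ref, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(ref, cur_start, cur_end))
    return merged


def span_of(intervals: Sequence[GenomicInterval]) -> tuple[str, int]:
    """Smallest (ref_name, start) over a set of intervals; a deterministic sort key."""
    first = min(intervals, key=lambda i: (i.ref_name, i.start, i.end))
    return first.ref_name, first.start
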