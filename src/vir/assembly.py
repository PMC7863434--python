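"""Greedy overlap-layout consensus for junction and LT reconstruction.

A deterministic, dependency-free micro-assembler with the same contract as a
local de-novo assembler: given the handful of reads recruited around a
junction, produce consensus contigs. Reads are considered in both
orientations; a contig is seeded from the longest unused read and extended
on either end by the read with the longest acceptable suffix-prefix overlap
(exact by default; mismatch-tolerant down to ``min_identity`` for data with
sequencing errors). Candidate overlaps are anchored with short exact seeds
so the search stays fast. Reads fully contained in the contig are absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import revcomp

ANCHOR = 16


@dataclass
class Contig:
    sequence: str
    read_ids: list[str] = field(default_factory=list)
    fragmentary: bool = False

    @property
    def read_count(self) -> int:
        return len(self.read_ids)


@dataclass
class AssemblyConfig:
    min_overlap: int = 30
    min_identity: float = 0.9  # within overlaps; exact overlaps always accepted


def _mismatches(a: str, b: str, budget: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def _candidate_offsets(contig: str, read: str, anchors: Sequence[int]) -> set[int]:
    """Offsets of ``read`` relative to contig start, inferred from exact
    ANCHOR-mers of the read found in the contig."""
    offsets: set[int] = set()
    for a in anchors:
        if a + ANCHOR > len(read):
            continue
        probe = read[a : a + ANCHOR]
        start = contig.find(probe)
        while start != -1:
            offsets.add(start - a)
            start = contig.find(probe, start + 1)
    return offsets


def _evaluate_placement(contig: str, read: str, cfg: AssemblyConfig) -> Optional[tuple[int, int]]:
    """Best placement of ``read`` against ``contig``.

    Returns (overlap_length, offset) where offset may be negative (read
    hangs off the left end) or beyond the contig (right end); None when no
    placement meets the overlap/identity requirements.
    """
    anchors = (0, 8, 16, 24, max(0, len(read) - ANCHOR))
    best: Optional[tuple[int, int]] = None
    for off in sorted(_candidate_offsets(contig, read, anchors)):
        lo = max(0, off)
        hi = min(len(contig), off + len(read))
        overlap = hi - lo
        if overlap < cfg.min_overlap:
            continue
        budget = int((1 - cfg.min_identity) * overlap)
        mm = _mismatches(contig[lo:hi], read[lo - off : hi - off], budget)
        if mm > budget:
            continue
        if best is None or overlap > best[0]:
            best = (overlap, off)
    return best


def greedy_assemble(
    reads: Sequence[tuple[str, str]],
    config: Optional[AssemblyConfig] = None,
) -> list[Contig]:
    """Assemble (read_id, sequence) pairs into consensus contigs.

    Deterministic: reads are processed sorted by id; seeds are the longest
    unused reads; on ties the smallest id wins. On overlap mismatches the
    contig base is kept (first-come consensus), which at error rate 0 makes
    every contig an exact substring of the underlying molecule.
    """
    cfg = config or AssemblyConfig()
    ordered = sorted({rid: seq.upper() for rid, seq in reads}.items())
    unused: dict[str, str] = dict(ordered)
    contigs: list[Contig] = []
    while unused:
        seed_id = min(unused, key=lambda rid: (-len(unused[rid]), rid))
        contig = unused.pop(seed_id)
        used_ids = [seed_id]
        grew = True
        while grew and unused:
            grew = False
            best: Optional[tuple[tuple, str, str, int]] = None
            for rid in sorted(unused):
                for orient, seq in (("+", unused[rid]), ("-", revcomp(unused[rid]))):
                    placed = _evaluate_placement(contig, seq, cfg)
                    if placed is None:
                        continue
                    overlap, off = placed
                    extension = max(0, -off) + max(0, off + len(seq) - len(contig))
                    # prefer most-overlapping placements; absorb containments first
                    key = (-overlap, extension, rid, orient)
                    if best is None or key < best[0]:
                        best = (key, rid, orient, off)
            if best is None:
                break
            _, rid, orient, off = best
            seq = unused.pop(rid) if orient == "+" else revcomp(unused.pop(rid))
            left = seq[: -off] if off < 0 else ""
            overhang = off + len(seq) - len(contig)
            right = seq[len(seq) - overhang :] if overhang > 0 else ""
            contig = left + contig + right
            used_ids.append(rid)
            grew = True
        contigs.append(Contig(sequence=contig, read_ids=sorted(used_ids)))
    contigs.sort(key=lambda c: (-len(c.sequence), c.read_ids[0] if c.read_ids else ""))
    if len(contigs) > 1:
        for c in contigs:
            c.fragmentary = True
    return contigs
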