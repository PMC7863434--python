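"""Realignment of a read group to its equivalent region and junction calling.

Each group's reads (host mates and their viral mates) are realigned to the
sequence of the group's equivalent region, which is the only reference in
this step: a viral mate that finds no acceptable local alignment there is
treated as unmapped for flag composition. Pair flags then vote on the side
of the integration — a forward-mapped host mate with an unmapped mate
supports the right end of the insertion (canonical flag pair 73/133), a
reverse-mapped host mate the left end (185/117). Breakpoints come from the
innermost mapped host-mate boundary, refined by soft-clip positions when
junction-spanning reads exist, and a greedy overlap consensus of each side's
reads stands in for an external assembler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (
    DEFAULT_SCORING,
    FLAG_UNMAPPED,
    FLAG_REVERSE,
    AlignmentRecord,
    Scoring,
    classify_pair_flags,
    local_align,
)
from .assembly import AssemblyConfig, greedy_assemble
from .dispersion import ReadGroup
from .intervals import GenomicInterval
from .refine import ChimericPair

SIDE_LEFT = "left"
SIDE_RIGHT = "right"
SIDE_UNINFORMATIVE = "uninformative"

RESOLVED_BOTH = "both"
RESOLVED_LEFT = "left_only"
RESOLVED_RIGHT = "right_only"


@dataclass
class GroupAlignConfig:
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)
    min_clip: int = 20  # soft-clip length that counts as junction evidence
    min_overlap: int = 30  # consensus overlap for the junction assembler
    assembly_identity: float = 0.9


@dataclass
class RealignedPair:
    pair: ChimericPair
    host_rec: Optional[AlignmentRecord]
    viral_rec: Optional[AlignmentRecord]
    flag_host: int
    flag_viral: int

    @property
    def side(self) -> str:
        return side_from_flags(self.flag_host, self.flag_viral)


@dataclass
class IntegrationCall:
    group_id: str
    region: list[GenomicInterval]
    viral_species: str
    left_support: int
    right_support: int
    breakpoint_left: Optional[int]
    breakpoint_right: Optional[int]
    left_consensus: str
    right_consensus: str
    resolved: str
    annotations: list[str] = field(default_factory=list)


def side_from_flags(flag_host: int, flag_viral: int) -> str:
    """Side of the integration supported by a realigned pair's flags.

    Host mate mapped forward + mate unmapped-on-region -> right end; host
    mate mapped reverse + mate unmapped -> left end; anything else (both
    mapped, both unmapped) is uninformative. Only the unmapped and strand
    bits matter; duplicate/QC bits never change the call.
    """
    host_mapped = not flag_host & FLAG_UNMAPPED
    viral_mapped = not flag_viral & FLAG_UNMAPPED
    if not host_mapped or viral_mapped:
        return SIDE_UNINFORMATIVE
    return SIDE_LEFT if flag_host & FLAG_REVERSE else SIDE_RIGHT


def realign_group(
    group: ReadGroup,
    region_seq: str,
    pairs: Sequence[ChimericPair],
    config: Optional[GroupAlignConfig] = None,
) -> list[RealignedPair]:
    """Realign each member pair's mates independently to the region sequence
    and compose SAM-style flags. The region is the only reference here."""
    if not region_seq:
        raise ValueError("region sequence is empty")
    config = config or GroupAlignConfig()
    by_id = {p.pair_id: p for p in pairs}
    out: list[RealignedPair] = []
    for pid in sorted(group.member_pair_ids):
        pair = by_id[pid]
        host_rec = local_align(pair.row.host_read_seq, region_seq, config.scoring,
                               ref_name=group.group_id, read_id=pid + "/h")
        viral_rec = local_align(pair.row.viral_read_seq, region_seq, config.scoring,
                                ref_name=group.group_id, read_id=pid + "/v")
        if host_rec is None and viral_rec is None:
            fh = fv = None
            flag_host, flag_viral = 0x1 | 0x4 | 0x8 | 0x40, 0x1 | 0x4 | 0x8 | 0x80
        else:
            flag_host, flag_viral = classify_pair_flags(host_rec, viral_rec, "first")
        out.append(RealignedPair(pair, host_rec, viral_rec, flag_host, flag_viral))
    return out


def assemble_junction(
    side_reads: Sequence[tuple[str, str]],
    min_overlap: int = 30,
    min_identity: float = 0.9,
) -> tuple[str, bool]:
    """Greedy overlap consensus of one side's reads.

    Returns (consensus, fragmentary); the consensus is empty when there are
    no reads, and the longest contig flagged fragmentary when the reads do
    not chain into a single contig.
    """
    if not side_reads:
        return "", False
    contigs = greedy_assemble(side_reads, AssemblyConfig(min_overlap, min_identity))
    return contigs[0].sequence, contigs[0].fragmentary or len(side_reads) == 1


def write_realignment_sam(
    realigned: Sequence[RealignedPair],
    region_name: str,
    region_length: int,
    path,
) -> None:
    """Emit the group realignment as SAM against the region sequence (both
    mates of every pair, unmapped mates included with their composed flags)."""
    from dataclasses import replace as dc_replace

    from .io import write_sam

    records = []
    for rp in realigned:
        mates = (
            (rp.host_rec, rp.pair.row.host_read_seq, rp.flag_host, "/h"),
            (rp.viral_rec, rp.pair.row.viral_read_seq, rp.flag_viral, "/v"),
        )
        for rec, seq, flag, suffix in mates:
            if rec is None:
                rec = AlignmentRecord(rp.pair.pair_id + suffix, region_name,
                                      0, 1, "+", flag | FLAG_UNMAPPED, [],
                                      0, 0.0)
            else:
                rec = dc_replace(rec, read_id=rp.pair.pair_id + suffix, flag=flag)
            records.append((rec, seq))
    write_sam(path, records, [(region_name, region_length)])


def _clip_breakpoints(realigned: Sequence[RealignedPair], min_clip: int) -> tuple[list[int], list[int]]:
    """Soft-clip junction candidates: a trailing clip marks a right-end
    breakpoint at the alignment end, a leading clip a left-end breakpoint."""
    right: list[int] = []
    left: list[int] = []
    for rp in realigned:
        for rec in (rp.host_rec, rp.viral_rec):
            if rec is None:
                continue
            if rec.trailing_clip >= min_clip:
                right.append(rec.end)
            if rec.leading_clip >= min_clip:
                left.append(rec.start)
    return right, left


def _mode(values: list[int]) -> Optional[int]:
    if not values:
        return None
    counts = Counter(values)
    return min(counts, key=lambda v: (-counts[v], v))


def call_integration(
    group: ReadGroup,
    region_seq: str,
    pairs: Sequence[ChimericPair],
    config: Optional[GroupAlignConfig] = None,
    region_origin: Optional[GenomicInterval] = None,
    realigned: Optional[Sequence[RealignedPair]] = None,
) -> Optional[IntegrationCall]:
    """Turn one group's realignment into an integration call.

    Side support comes from pair flags. The right breakpoint is the maximum
    end of forward host mates, the left the minimum start of reverse host
    mates; soft-clip evidence overrides those bounds when spanning reads
    exist. ``region_origin`` maps region-local positions back to genome
    coordinates. A precomputed realignment may be supplied; otherwise the
    group is realigned here. Returns None when no pair is informative.
    """
    config = config or GroupAlignConfig()
    if realigned is None:
        realigned = realign_group(group, region_seq, pairs, config)
    right_pairs = [rp for rp in realigned if rp.side == SIDE_RIGHT]
    left_pairs = [rp for rp in realigned if rp.side == SIDE_LEFT]
    if not right_pairs and not left_pairs:
        return None

    bp_right = max((rp.host_rec.end for rp in right_pairs), default=None)
    bp_left = min((rp.host_rec.start for rp in left_pairs), default=None)
    clip_right, clip_left = _clip_breakpoints(realigned, config.min_clip)
    if clip_right:
        bp_right = _mode(clip_right)
    if clip_left:
        bp_left = _mode(clip_left)

    def side_reads(rps: Sequence[RealignedPair]) -> list[tuple[str, str]]:
        reads = []
        for rp in rps:
            reads.append((rp.pair.pair_id + "/h", rp.pair.row.host_read_seq))
            reads.append((rp.pair.pair_id + "/v", rp.pair.row.viral_read_seq))
        return reads

    acfg = (config.min_overlap, config.assembly_identity)
    right_consensus, _ = assemble_junction(side_reads(right_pairs), *acfg)
    left_consensus, _ = assemble_junction(side_reads(left_pairs), *acfg)

    if right_pairs and left_pairs:
        resolved = RESOLVED_BOTH
    elif right_pairs:
        resolved = RESOLVED_RIGHT
    else:
        resolved = RESOLVED_LEFT

    offset = region_origin.start if region_origin is not None else 0
    return IntegrationCall(
        group_id=group.group_id,
        region=list(group.loci),
        viral_species=group.viral_species,
        left_support=len(left_pairs),
        right_support=len(right_pairs),
        breakpoint_left=None if bp_left is None else bp_left + offset,
        breakpoint_right=None if bp_right is None else bp_right + offset,
        left_consensus=left_consensus,
        right_consensus=right_consensus,
        resolved=resolved,
        annotations=list(group.annotations),
    )
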