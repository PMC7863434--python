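"""Grouping of host reads that map to equivalent genomic regions.

Host reads supporting the same junction disperse across every copy of a
repeat (or across mis-assembled duplicates). Here all primary and secondary
host-read loci are merged into regions (intervals whose gap is <= 1000 bp by
default), a read group is formed per (region, viral species) with at least 2
members, and groups sharing more than 80% of their reads (denominator: the
smaller group) are collapsed iteratively to a fixed point. Reads left in no
emitted group are reported as ungrouped — they cannot support an integration
but are retained so downstream statistics can count them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .align import AlignmentRecord
from .intervals import GenomicInterval, merge_intervals, span_of
from .refine import ChimericPair


@dataclass
class DispersionConfig:
    max_read_distance: int = 1000
    min_reads_per_region: int = 2
    merge_share_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.max_read_distance <= 0 or self.min_reads_per_region <= 0:
            raise ValueError("distances and read counts must be positive")
        if not (0 < self.merge_share_threshold <= 1):
            raise ValueError("merge_share_threshold must be in (0, 1]")


@dataclass
class ReadGroup:
    group_id: str
    member_pair_ids: set[str]
    loci: list[GenomicInterval]
    viral_species: str
    merged_from: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_pair_ids)

    def sort_key(self) -> tuple:
        key = getattr(self, "_sort_key", None)
        if key is None:
            key = span_of(self.loci)
            object.__setattr__(self, "_sort_key", key)
        return key


@dataclass
class DispersionResult:
    groups: list[ReadGroup]
    ungrouped: list[str]  # pair ids
    membership: dict[str, str]  # pair id -> final group id
    locus_by_pair: dict[str, GenomicInterval]  # pre-grouping locus (upstream caller)


def collect_host_loci(
    pairs: Sequence[ChimericPair],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
) -> dict[str, list[GenomicInterval]]:
    """Every primary and secondary host-read alignment becomes a locus;
    duplicates are collapsed. A pair absent from the alignment map errors."""
    out: dict[str, list[GenomicInterval]] = {}
    for pair in pairs:
        recs = alignments.get(pair.pair_id) or pair.host_alignments
        if not recs:
            raise KeyError(f"pair {pair.pair_id} has no host alignment in the SAM")
        seen = {}
        for rec in recs:
            seen[GenomicInterval(rec.ref_name, rec.start, rec.end)] = None
        out[pair.pair_id] = sorted(seen)
    return out


def merge_loci_into_regions(
    loci_by_pair: Mapping[str, Sequence[GenomicInterval]],
    species_by_pair: Mapping[str, str],
    config: DispersionConfig,
) -> tuple[list[ReadGroup], list[str]]:
    """Initial groups: one per (merged region, viral species).

    A pair belongs to every region containing at least one of its loci, so a
    multi-mapping read seeds a group at each repeat copy; the pairwise merge
    collapses the redundancy afterwards. Groups below the minimum read count
    are not emitted; pairs in no emitted group are returned as ungrouped.
    """
    all_loci = [iv for ivs in loci_by_pair.values() for iv in ivs]
    if not all_loci:
        return [], sorted(loci_by_pair)
    regions = merge_intervals(all_loci, gap=config.max_read_distance)
    by_ref: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
    for region in regions:
        starts, ivs = by_ref.setdefault(region.ref_name, ([], []))
        starts.append(region.start)
        ivs.append(region)

    members: dict[tuple[GenomicInterval, str], set[str]] = {}
    for pair_id, ivs in loci_by_pair.items():
        species = species_by_pair[pair_id]
        for iv in ivs:
            starts, regs = by_ref[iv.ref_name]
            i = bisect.bisect_right(starts, iv.start) - 1
            region = regs[i]
            members.setdefault((region, species), set()).add(pair_id)

    groups: list[ReadGroup] = []
    grouped: set[str] = set()
    keys = sorted(members, key=lambda k: (k[0].ref_name, k[0].start, k[1]))
    for n, (region, species) in enumerate(keys):
        ids = members[(region, species)]
        if len(ids) < config.min_reads_per_region:
            continue
        groups.append(ReadGroup(
            group_id=f"g{n:04d}",
            member_pair_ids=set(ids),
            loci=[region],
            viral_species=species,
        ))
        grouped |= ids
    ungrouped = sorted(set(loci_by_pair) - grouped)
    return groups, ungrouped


def _shared_fraction(a: ReadGroup, b: ReadGroup) -> float:
    inter = len(a.member_pair_ids & b.member_pair_ids)
    return inter / min(len(a.member_pair_ids), len(b.member_pair_ids))


def merge_read_groups(groups: Sequence[ReadGroup], config: DispersionConfig) -> list[ReadGroup]:
    """Collapse groups sharing strictly more than the threshold fraction of
    reads (denominator: the smaller group), iterated to a fixed point.

    The highest-sharing pair (same species only) merges first; ties go to the
    smaller combined genomic coordinate, making the process deterministic.
    Termination is guaranteed because each merge removes one group.
    """
    pool = [ReadGroup(g.group_id, set(g.member_pair_ids), list(g.loci),
                      g.viral_species, list(g.merged_from) or [g.group_id], list(g.annotations))
            for g in groups]
    while len(pool) > 1:
        best: Optional[tuple] = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                a, b = pool[i], pool[j]
                if a.viral_species != b.viral_species:
                    continue
                share = _shared_fraction(a, b)
                if share <= config.merge_share_threshold:
                    continue
                key = (-share, min(a.sort_key(), b.sort_key()), max(a.sort_key(), b.sort_key()))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = pool[i], pool[j]
        first, second = sorted((a, b), key=lambda g: g.sort_key())
        merged = ReadGroup(
            group_id=first.group_id,
            member_pair_ids=a.member_pair_ids | b.member_pair_ids,
            loci=merge_intervals(a.loci + b.loci, gap=0),
            viral_species=a.viral_species,
            merged_from=first.merged_from + second.merged_from,
            annotations=sorted(set(a.annotations) | set(b.annotations)),
        )
        pool = [g for k, g in enumerate(pool) if k not in (i, j)] + [merged]
    pool.sort(key=lambda g: g.sort_key())
    return pool


def assign_unique_membership(
    groups: Sequence[ReadGroup],
    loci_by_pair: Mapping[str, Sequence[GenomicInterval]],
    config: DispersionConfig,
) -> tuple[list[ReadGroup], dict[str, str], list[str]]:
    """Give every pair exactly one final home.

    After the fixed point, a pair may still sit in two groups sharing less
    than the threshold; it is assigned to the group containing most of its
    loci (ties: smaller group coordinate). Groups falling below the minimum
    size lose their members to the ungrouped list.
    """
    claimed: dict[str, list[ReadGroup]] = {}
    for g in groups:
        for pid in g.member_pair_ids:
            claimed.setdefault(pid, []).append(g)
    membership: dict[str, str] = {}
    for pid, gs in claimed.items():
        if len(gs) == 1:
            membership[pid] = gs[0].group_id
            continue
        def contained(g: ReadGroup) -> int:
            return sum(
                1 for iv in loci_by_pair.get(pid, [])
                if any(reg.overlaps(iv) for reg in g.loci)
            )
        best = min(gs, key=lambda g: (-contained(g), g.sort_key()))
        membership[pid] = best.group_id
    final: list[ReadGroup] = []
    ungrouped: list[str] = []
    for g in groups:
        mine = {pid for pid in g.member_pair_ids if membership.get(pid) == g.group_id}
        if len(mine) >= config.min_reads_per_region:
            final.append(ReadGroup(g.group_id, mine, g.loci, g.viral_species,
                                   g.merged_from, g.annotations))
        else:
            ungrouped.extend(sorted(mine))
            for pid in mine:
                membership.pop(pid, None)
    final.sort(key=lambda g: g.sort_key())
    return final, membership, sorted(ungrouped)


def annotate_groups(
    groups: Iterable[ReadGroup],
    annotations: Sequence[tuple[GenomicInterval, str]],
) -> None:
    """Attach every annotation label overlapping any group locus (e.g. known
    EVEs or TEs, used to tell EVE polymorphisms from new integrations)."""
    trees: dict[str, IntervalTree] = {}
    for iv, label in annotations:
        trees.setdefault(iv.ref_name, IntervalTree()).addi(iv.start, iv.end, label)
    for group in groups:
        labels: set[str] = set(group.annotations)
        for locus in group.loci:
            tree = trees.get(locus.ref_name)
            if tree is None:
                continue
            for hit in tree.overlap(locus.start, locus.end):
                labels.add(hit.data)
        group.annotations = sorted(labels)


def solve_dispersion_sample(
    kept_pairs: Sequence[ChimericPair],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    config: Optional[DispersionConfig] = None,
    annotations: Sequence[tuple[GenomicInterval, str]] = (),
) -> DispersionResult:
    """Run the three grouping steps for one sample."""
    config = config or DispersionConfig()
    if not kept_pairs:
        return DispersionResult([], [], {}, {})
    loci_by_pair = collect_host_loci(kept_pairs, alignments)
    species = {p.pair_id: p.row.viral_ref for p in kept_pairs}
    initial, _ = merge_loci_into_regions(loci_by_pair, species, config)
    merged = merge_read_groups(initial, config)
    final, membership, ungrouped = assign_unique_membership(merged, loci_by_pair, config)
    ungrouped = sorted(set(loci_by_pair) - set(membership))
    if annotations:
        annotate_groups(final, annotations)
    locus_by_pair = {p.pair_id: p.row.host_locus for p in kept_pairs}
    return DispersionResult(final, ungrouped, membership, locus_by_pair)


def solve_dispersion(
    samples: Mapping[str, tuple[Sequence[ChimericPair], Mapping[str, Sequence[AlignmentRecord]]]],
    config: Optional[DispersionConfig] = None,
    annotations: Sequence[tuple[GenomicInterval, str]] = (),
) -> dict[str, DispersionResult]:
    """Per-sample orchestration; samples are processed independently."""
    return {
        sample: solve_dispersion_sample(pairs, alns, config, annotations)
        for sample, (pairs, alns) in samples.items()
    }
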