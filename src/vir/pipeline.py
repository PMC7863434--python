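"""End-to-end orchestration of the chimeric-pair route (module 1).

chimera scan -> candidate refinement -> dispersion solving -> per-group
realignment and integration calling, plus the per-sample dispersion-gain
report. This is the path the benchmark and the CLI drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import SeedIndex
from .dispersion import DispersionConfig, DispersionResult, ReadGroup, solve_dispersion_sample
from .gain import GainReport, gain_report
from .group_align import (
    GroupAlignConfig,
    IntegrationCall,
    call_integration,
    realign_group,
    write_realignment_sam,
)
from .intervals import GenomicInterval
from .refine import RefineConfig, RefineResult, refine_candidates
from .simulate import HOST_REF, ReadSet, ScanConfig, ScanResult, chimera_scan


@dataclass
class Module1Config:
    scan: ScanConfig = field(default_factory=ScanConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    dispersion: DispersionConfig = field(default_factory=DispersionConfig)
    group_align: GroupAlignConfig = field(default_factory=GroupAlignConfig)
    region_pad: int = 200  # context added around the representative interval


@dataclass
class Module1Result:
    scan: ScanResult
    refine: RefineResult
    dispersion: DispersionResult
    calls: list[IntegrationCall]
    gain: Optional[GainReport]

    @property
    def stopped(self) -> bool:
        return self.refine.stop_message is not None


def representative_interval(group: ReadGroup, pairs) -> GenomicInterval:
    """The anchor copy the group's reads are realigned against.

    Each group locus is scored by how many member host reads have an
    alignment inside it; reads touching the unique flank of the true copy
    map only there, so the true copy collects the most members (ties go to
    the widest, then smallest-coordinate interval).
    """
    by_id = {p.pair_id: p for p in pairs}
    counts = {iv: 0 for iv in group.loci}
    for pid in group.member_pair_ids:
        pair = by_id[pid]
        placements = [rec.interval for rec in pair.host_alignments] or [pair.row.host_locus]
        for iv in group.loci:
            if any(iv.overlaps(p) for p in placements):
                counts[iv] += 1
    return min(counts, key=lambda iv: (-counts[iv], -iv.length, iv.ref_name, iv.start))


def run_module1(
    reads: ReadSet,
    host_genome: str,
    viral_genome: str,
    config: Optional[Module1Config] = None,
    sample_id: str = "sample",
    annotations: Sequence[tuple[GenomicInterval, str]] = (),
    host_index: Optional[SeedIndex] = None,
    realign_sam_dir: Optional[str] = None,
) -> Module1Result:
    cfg = config or Module1Config()
    scan = chimera_scan(reads, host_genome, viral_genome, cfg.scan,
                        sample_id=sample_id, host_index=host_index)
    host = {HOST_REF: host_genome}
    indexes = {HOST_REF: scan.host_index}
    refined = refine_candidates(scan.rows, scan.host_alignments, host,
                                cfg.refine, indexes=indexes)
    disp = solve_dispersion_sample(refined.kept, scan.host_alignments,
                                   cfg.dispersion, annotations)
    calls: list[IntegrationCall] = []
    for group in disp.groups:
        rep = representative_interval(group, refined.kept)
        start = max(0, rep.start - cfg.region_pad)
        end = min(len(host_genome), rep.end + cfg.region_pad)
        region_seq = host_genome[start:end]
        origin = GenomicInterval(rep.ref_name, start, end) if end > start else None
        members = [p for p in refined.kept if p.pair_id in group.member_pair_ids]
        realigned = realign_group(group, region_seq, members, cfg.group_align)
        if realign_sam_dir is not None:
            import os

            write_realignment_sam(
                realigned, group.group_id, len(region_seq),
                os.path.join(realign_sam_dir, f"realign_{group.group_id}.sam"))
        call = call_integration(group, region_seq, members, cfg.group_align,
                                region_origin=origin, realigned=realigned)
        if call is not None:
            calls.append(call)
    gain = gain_report(sample_id, disp)
    return Module1Result(scan=scan, refine=refined, dispersion=disp, calls=calls, gain=gain)
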