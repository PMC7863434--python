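"""Lateral-transfer finder: recruit reads matching a non-host sequence and
assemble them locally into a consensus with host flanks.

Runs independently of the chimeric-pair route. Every read pair of a WGS
sample is screened against the non-host (e.g. viral) sequence; a pair is
recruited when either mate has a local alignment with identity >= 0.8 over
>= 30 nt, and the mate of a recruited read is always carried along.
Recruited pairs fall into three categories: both mates essentially viral,
chimeric pairs (one viral mate, one host mate), and soft-clipped reads whose
alignment covers only part of the read — the clipped remainder spans the
junction. A greedy overlap assembly of the recruited reads reconstructs the
transferred sequence; each contig is annotated with its non-host match span
and the left/right host flank lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .align import (
    AlignmentRecord,
    Scoring,
    build_seed_index,
    local_align,
)
from .assembly import AssemblyConfig, Contig, greedy_assemble
from .io import write_fasta, write_sam
from .simulate import ReadSet, ScanConfig, _viral_hit_counts, rolling_viral_kmers

CAT_BOTH_VIRAL = "both_viral"
CAT_CHIMERIC = "chimeric_mate"
CAT_SOFT_CLIPPED = "soft_clipped"


@dataclass
class LTConfig:
    min_identity: float = 0.80
    min_span: int = 30
    full_cover_fraction: float = 0.8  # alignment covering >= this is "fully viral"
    min_overlap: int = 30
    assembly_identity: float = 0.9
    screen_k: int = 13
    screen_stride: int = 4
    screen_min_hits: int = 2


@dataclass
class RecruitedPair:
    pair_id: str
    seq1: str
    seq2: str
    category: str
    alignments: tuple[Optional[AlignmentRecord], Optional[AlignmentRecord]]


@dataclass
class RecruitedReadSet:
    pairs: list[RecruitedPair]
    nonhost_name: str

    def reads(self) -> list[tuple[str, str]]:
        out = []
        for p in self.pairs:
            out.append((p.pair_id + "/1", p.seq1))
            out.append((p.pair_id + "/2", p.seq2))
        return out


@dataclass
class LTContig:
    sequence: str
    supporting_reads: int
    nonhost_span: Optional[tuple[int, int]]  # on the contig
    flank_left: int
    flank_right: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def nonhost_length(self) -> int:
        if self.nonhost_span is None:
            return 0
        return self.nonhost_span[1] - self.nonhost_span[0]


def recruit_reads(
    reads: Union[ReadSet, Sequence[tuple[str, str, str]]],
    nonhost: dict[str, str],
    config: Optional[LTConfig] = None,
) -> RecruitedReadSet:
    """Recruit pairs in which at least one mate aligns to the non-host
    sequence with identity >= min_identity over >= min_span nucleotides.

    Recruitment is monotone in min_identity: lowering the threshold can only
    add pairs. Categories follow the alignment geometry of the qualifying
    mates (both viral / chimeric mate / soft clipped).
    """
    cfg = config or LTConfig()
    if not nonhost or not any(nonhost.values()):
        raise ValueError("non-host FASTA is empty")
    name, target = next(iter(nonhost.items()))
    if isinstance(reads, ReadSet):
        rs = reads
    else:
        rs = ReadSet.from_pairs(list(reads))
    index = build_seed_index(target, cfg.screen_k)
    kmers = np.unique(rolling_viral_kmers(target, cfg.screen_k))
    screen_cfg = ScanConfig(k=cfg.screen_k, stride=cfg.screen_stride)
    hits1 = _viral_hit_counts(rs.r1, kmers, screen_cfg)
    hits2 = _viral_hit_counts(rs.r2, kmers, screen_cfg)
    candidates = np.nonzero((hits1 >= cfg.screen_min_hits) | (hits2 >= cfg.screen_min_hits))[0]
    scoring = Scoring(min_score=cfg.min_span // 2, min_identity=cfg.min_identity)
    recruited: list[RecruitedPair] = []
    for i in candidates:
        pid, s1, s2 = rs.pair_seqs(int(i))
        recs = []
        for seq in (s1, s2):
            rec = local_align(seq, target, scoring, index=index, ref_name=name, read_id=pid)
            if rec is not None:
                span = rec.query_end - rec.query_start
                if span < cfg.min_span or rec.identity < cfg.min_identity:
                    rec = None
            recs.append(rec)
        if recs[0] is None and recs[1] is None:
            continue

        def covered(rec: Optional[AlignmentRecord], seq: str) -> float:
            if rec is None:
                return 0.0
            return (rec.query_end - rec.query_start) / len(seq)

        cov1, cov2 = covered(recs[0], s1), covered(recs[1], s2)
        full = cfg.full_cover_fraction
        if cov1 >= full and cov2 >= full:
            category = CAT_BOTH_VIRAL
        elif (recs[0] is not None and cov1 < full) or (recs[1] is not None and cov2 < full):
            category = CAT_SOFT_CLIPPED
        else:
            category = CAT_CHIMERIC
        recruited.append(RecruitedPair(pid, s1, s2, category, (recs[0], recs[1])))
    return RecruitedReadSet(pairs=recruited, nonhost_name=name)


def assemble_recruited(
    recruited: RecruitedReadSet,
    nonhost: dict[str, str],
    config: Optional[LTConfig] = None,
) -> list[LTContig]:
    """Greedy overlap assembly of all recruited reads; contigs are annotated
    with the non-host match span and flank lengths by aligning each contig
    back to the non-host sequence. 0 or 1 recruited pairs produce no contig."""
    cfg = config or LTConfig()
    reads = recruited.reads()
    if len(recruited.pairs) < 1:
        return []
    contigs = greedy_assemble(reads, AssemblyConfig(cfg.min_overlap, cfg.assembly_identity))
    target = nonhost[recruited.nonhost_name]
    index = build_seed_index(target, cfg.screen_k) if len(target) >= cfg.screen_k else None
    out: list[LTContig] = []
    for c in contigs:
        if c.read_count < 2:
            continue
        rec = local_align(c.sequence, target, Scoring(min_score=cfg.min_span),
                          index=index, ref_name=recruited.nonhost_name, read_id="contig")
        if rec is None:
            span = None
            left = right = 0
        else:
            if rec.strand == "-":
                qlen = len(c.sequence)
                span = (qlen - rec.query_end, qlen - rec.query_start)
            else:
                span = (rec.query_start, rec.query_end)
            left, right = span[0], len(c.sequence) - span[1]
        out.append(LTContig(
            sequence=c.sequence,
            supporting_reads=c.read_count,
            nonhost_span=span,
            flank_left=left,
            flank_right=right,
            read_ids=c.read_ids,
        ))
    return out


def lt_report(
    contigs: Sequence[LTContig],
    recruited: RecruitedReadSet,
    out_prefix: str,
) -> dict:
    """Emit contig FASTA, recruited-read alignments against the contigs as
    SAM (IGV-loadable), and a TSV of contig/flank statistics."""
    import pandas as pd

    names = {f"lt_contig_{i}": c for i, c in enumerate(contigs)}
    write_fasta({n: c.sequence for n, c in names.items()}, out_prefix + ".contigs.fasta")
    sam_records = []
    scoring = Scoring(min_score=20)
    for rid, seq in recruited.reads():
        best = None
        best_name = None
        for n, c in names.items():
            rec = local_align(seq, c.sequence, scoring, ref_name=n, read_id=rid)
            if rec is not None and (best is None or rec.score > best.score):
                best, best_name = rec, n
        if best is not None:
            sam_records.append((best, seq))
    write_sam(
        out_prefix + ".reads.sam",
        sam_records,
        [(n, len(c.sequence)) for n, c in names.items()],
    )
    rows = [{
        "contig": n,
        "length": len(c.sequence),
        "supporting_reads": c.supporting_reads,
        "nonhost_start": c.nonhost_span[0] if c.nonhost_span else ".",
        "nonhost_end": c.nonhost_span[1] if c.nonhost_span else ".",
        "flank_left": c.flank_left,
        "flank_right": c.flank_right,
    } for n, c in names.items()]
    df = pd.DataFrame(rows, columns=["contig", "length", "supporting_reads",
                                     "nonhost_start", "nonhost_end",
                                     "flank_left", "flank_right"])
    df.to_csv(out_prefix + ".report.tsv", sep="\t", index=False)
    return {"contigs": len(contigs), "reads": len(sam_records)}
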