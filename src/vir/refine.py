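"""Selection of "best candidate" chimeric pairs.

Three filters are applied in order: (1) sequence complexity of the viral
mate, expressed as the maximal fraction of positions covered by a single
dinucleotide (keep if < 0.80); (2) minimum viral span (keep if >= 30 nt);
(3) a proximity filter that drops pairs whose viral mate can be locally
aligned to the host genome within +/-10,000 bp of any locus of the host
mate — such a "viral" read is explainable by nearby host sequence.
Each dropped pair is attributed to the first failing criterion; the filters
themselves are pure predicates, so the surviving set is order-insensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .align import AlignmentRecord, DEFAULT_SCORING, Scoring, SeedIndex, build_seed_index, encode, revcomp_codes, rolling_kmer_codes
from .intervals import GenomicInterval
from .io import ChimericTableRow

STATUS_KEPT = "kept"
STATUS_COMPLEXITY = "dropped_complexity"
STATUS_SHORT_VIRAL = "dropped_short_viral"
STATUS_PROXIMAL = "dropped_proximal"

STOP_MESSAGE = "No pair of reads passed the filtering steps."


@dataclass
class RefineConfig:
    max_dinucleotide_fraction: float = 0.80
    min_viral_span: int = 30
    proximity_window: int = 10_000
    test_both_mates: bool = False  # complexity filter on the host mate too
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)

    def __post_init__(self) -> None:
        if not (0 < self.max_dinucleotide_fraction <= 1):
            raise ValueError("max_dinucleotide_fraction must be in (0, 1]")
        if self.min_viral_span <= 0 or self.proximity_window <= 0:
            raise ValueError("min_viral_span and proximity_window must be positive")


@dataclass
class ChimericPair:
    row: ChimericTableRow
    host_alignments: list[AlignmentRecord] = field(default_factory=list)
    status: str = STATUS_KEPT

    @property
    def pair_id(self) -> str:
        return self.row.pair_id

    def host_loci(self) -> list[GenomicInterval]:
        """Distinct loci the host read can occupy (primary + secondary),
        falling back to the table's locus when no alignment is attached."""
        if not self.host_alignments:
            return [self.row.host_locus]
        seen = {}
        for rec in self.host_alignments:
            iv = GenomicInterval(rec.ref_name, rec.start, rec.end)
            seen[iv] = None
        return sorted(seen)


@dataclass
class RefineResult:
    kept: list[ChimericPair]
    dropped: list[ChimericPair]
    report: dict[str, int]
    stop_message: Optional[str] = None


def dinucleotide_coverage(seq: str) -> float:
    """Max over the 16 dinucleotides of the fraction of sequence positions
    covered by at least one overlapping occurrence of that dinucleotide.

    A pure AC-repeat and a homopolymer both score 1.0; invariant under
    reverse complement.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    seq = seq.upper()
    occurrences: dict[str, list[int]] = {}
    for i in range(n - 1):
        occurrences.setdefault(seq[i : i + 2], []).append(i)
    best = 0.0
    for dinuc, starts in occurrences.items():
        if len(set(dinuc)) > 2 or set(dinuc) - set("ACGT"):
            continue
        covered = 0
        prev_end = -1
        for s in starts:
            covered += min(2, s + 2 - max(s, prev_end))
            prev_end = s + 2
        best = max(best, covered / n)
    return best


def filter_complexity(pairs: Iterable[ChimericPair], config: RefineConfig) -> None:
    for pair in pairs:
        if pair.status != STATUS_KEPT:
            continue
        seqs = [pair.row.viral_read_seq]
        if config.test_both_mates:
            seqs.append(pair.row.host_read_seq)
        # strict "< 80%": a read at exactly the threshold is dropped
        if any(dinucleotide_coverage(s) >= config.max_dinucleotide_fraction for s in seqs):
            pair.status = STATUS_COMPLEXITY


def filter_viral_span(pairs: Iterable[ChimericPair], config: RefineConfig) -> None:
    for pair in pairs:
        if pair.status != STATUS_KEPT:
            continue
        if pair.row.viral_span < config.min_viral_span:
            pair.status = STATUS_SHORT_VIRAL


def _windows_have_seed_hit(
    viral_seq: str,
    loci: Sequence[GenomicInterval],
    indexes: Mapping[str, SeedIndex],
    window: int,
) -> list[tuple[str, int, int]]:
    """Windows (ref, start, end) around ``loci`` where the viral read has at
    least one exact seed hit on either strand."""
    fwd = encode(viral_seq)
    out = []
    per_ref_hits: dict[str, set[int]] = {}
    for ref in {iv.ref_name for iv in loci}:
        idx = indexes.get(ref)
        if idx is None:
            continue
        hits: set[int] = set()
        for q in (fwd, revcomp_codes(fwd)):
            codes = rolling_kmer_codes(q, idx.k)
            _, t_pos = idx.lookup_many(codes)
            hits.update(int(p) for p in t_pos)
        per_ref_hits[ref] = hits
    for iv in loci:
        hits = per_ref_hits.get(iv.ref_name)
        if not hits:
            continue
        lo, hi = iv.start - window, iv.end + window
        if any(lo <= h < hi for h in hits):
            out.append((iv.ref_name, max(0, lo), hi))
    return out


def filter_proximal_host_hit(
    pairs: Iterable[ChimericPair],
    host_genome: Mapping[str, str],
    config: RefineConfig,
    indexes: Optional[Mapping[str, SeedIndex]] = None,
) -> None:
    """Drop pairs whose viral mate aligns to the host genome within
    +/-window of any host-read locus (align_core minimum acceptance)."""
    from .align import local_align

    if indexes is None:
        indexes = {name: build_seed_index(seq) for name, seq in host_genome.items()}
    for pair in pairs:
        if pair.status != STATUS_KEPT:
            continue
        windows = _windows_have_seed_hit(
            pair.row.viral_read_seq, pair.host_loci(), indexes, config.proximity_window
        )
        for ref, lo, hi in windows:
            target = host_genome[ref][lo : min(hi, len(host_genome[ref]))]
            rec = local_align(pair.row.viral_read_seq, target, config.scoring)
            if rec is not None:
                pair.status = STATUS_PROXIMAL
                break


def refine_candidates(
    table: Sequence[ChimericTableRow],
    host_alignments: Mapping[str, Sequence[AlignmentRecord]],
    host_genome: Mapping[str, str],
    config: Optional[RefineConfig] = None,
    indexes: Optional[Mapping[str, SeedIndex]] = None,
) -> RefineResult:
    """Apply the three filters in order and report drop counts per reason.

    ``host_alignments`` maps a pair_id to all host-read alignments from the
    SAM (primary and secondary). An empty survivor set is a distinguished
    result carrying a stop message, not an error.
    """
    config = config or RefineConfig()
    pairs = [ChimericPair(row=row, host_alignments=list(host_alignments.get(row.pair_id, [])))
             for row in table]
    filter_complexity(pairs, config)
    filter_viral_span(pairs, config)
    filter_proximal_host_hit(pairs, host_genome, config, indexes)
    kept = [p for p in pairs if p.status == STATUS_KEPT]
    dropped = [p for p in pairs if p.status != STATUS_KEPT]
    report = dict(Counter(p.status for p in dropped))
    for key in (STATUS_COMPLEXITY, STATUS_SHORT_VIRAL, STATUS_PROXIMAL):
        report.setdefault(key, 0)
    return RefineResult(
        kept=kept,
        dropped=dropped,
        report=report,
        stop_message=STOP_MESSAGE if not kept else None,
    )
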