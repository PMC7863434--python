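"""Synthetic WGS benchmark generator and a minimal chimera scanner.

The generator reproduces the benchmark design this pipeline is evaluated
on: a host genome carrying a unique locus (UL), a 10-copy repeat (Rep10)
and a 100-copy repeat (Rep100); a 300/600/900 bp fragment of a viral
sequence spliced into one copy of a chosen class; 2x150 paired reads at
700 bp fragment length at coverages 5-60x; and pools of 10/30/50
individuals with exactly one integration carrier. Repeat copies are exact
by default — the worst case for read dispersion — with optional per-copy
divergence. Reads live in numpy code matrices (:class:`ReadSet`) so whole
samples can be screened vectorially; FASTQ is written on demand.

The chimera scanner stands in for an upstream chimeric-pair caller so the
pipeline is testable end to end: every pair is screened with viral k-mers,
candidates are aligned to both references, and a pair is emitted as
chimeric when one mate's best alignment is host (identity >= 0.9) and the
other's is virus (span >= 20 nt). The host-side SAM records carry all
near-best placements of the host mate, which is what lets the dispersion
stage see every repeat copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import (
    AlignmentRecord,
    DEFAULT_SCORING,
    Scoring,
    SeedIndex,
    build_seed_index,
    decode,
    encode,
    local_align,
    local_align_all,
    revcomp_codes,
)
from .intervals import GenomicInterval
from .io import ChimericTableRow, write_fastq

HOST_REF = "host1"
VIRUS_REF = "virus1"

REPEAT_CLASSES = {"UL": 1, "Rep10": 10, "Rep100": 100}


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    repeat_unit_length: int = 1000
    viral_length: int = 11_000
    insert_length: int = 600
    insert_class: str = "Rep10"
    read_length: int = 150
    fragment_length: int = 700
    fragment_sd: int = 50
    coverage: float = 30.0
    error_rate: float = 0.001
    pool_size: int = 1
    repeat_divergence: float = 0.0  # per-copy substitution rate
    insert_margin: int = 150  # keep the junction inside the repeat copy

    def __post_init__(self) -> None:
        if self.insert_length > self.viral_length:
            raise ValueError("insert_length exceeds the viral source length")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment length must be at least the read length")
        if self.insert_class not in REPEAT_CLASSES:
            raise ValueError(f"insert_class must be one of {sorted(REPEAT_CLASSES)}")


@dataclass
class SimTruth:
    sample_id: str
    carrier: bool
    insertion_point: Optional[int] = None  # reference (uninserted) coordinate
    insertion_interval: Optional[GenomicInterval] = None  # on the modified genome
    locus_class: Optional[str] = None
    insert_length: Optional[int] = None
    viral_span: Optional[GenomicInterval] = None  # on the viral source
    copy_interval: Optional[GenomicInterval] = None  # the repeat copy hit


@dataclass
class ReadSet:
    """Paired reads as (n_pairs, read_len) base-code matrices (0..3, 4=N)."""

    ids: list[str]
    r1: np.ndarray
    r2: np.ndarray
    individuals: Optional[list[str]] = None

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def pair_seqs(self, i: int) -> tuple[str, str, str]:
        return self.ids[i], decode(self.r1[i]), decode(self.r2[i])

    def iter_pairs(self):
        for i in range(self.n_pairs):
            yield self.pair_seqs(i)

    def to_fastq(self, path1, path2) -> None:
        comments = self.individuals or [""] * self.n_pairs
        write_fastq(
            ((f"{rid}/1" + (f" {c}" if c else ""), decode(self.r1[i]))
             for i, (rid, c) in enumerate(zip(self.ids, comments))),
            path1,
        )
        write_fastq(
            ((f"{rid}/2" + (f" {c}" if c else ""), decode(self.r2[i]))
             for i, (rid, c) in enumerate(zip(self.ids, comments))),
            path2,
        )

    @staticmethod
    def concat(parts: Sequence["ReadSet"]) -> "ReadSet":
        return ReadSet(
            ids=[rid for p in parts for rid in p.ids],
            r1=np.concatenate([p.r1 for p in parts]),
            r2=np.concatenate([p.r2 for p in parts]),
            individuals=[ind for p in parts for ind in (p.individuals or [""] * p.n_pairs)],
        )

    @staticmethod
    def from_pairs(pairs: Sequence[tuple[str, str, str]]) -> "ReadSet":
        if not pairs:
            empty = np.zeros((0, 1), np.uint8)
            return ReadSet([], empty, empty.copy())
        length = max(len(s) for _, s1, s2 in pairs for s in (s1, s2))
        n = len(pairs)
        r1 = np.full((n, length), 4, np.uint8)
        r2 = np.full((n, length), 4, np.uint8)
        ids = []
        for i, (rid, s1, s2) in enumerate(pairs):
            ids.append(rid)
            r1[i, : len(s1)] = encode(s1)
            r2[i, : len(s2)] = encode(s2)
        return ReadSet(ids, r1, r2)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def default_viral_source(length: int = 11_000) -> str:
    """The bundled synthetic viral sequence (deterministic; a stand-in for a
    real flavivirus genome, which can be supplied instead via FASTA)."""
    rng = np.random.default_rng(np.random.SeedSequence(0xD2B1C))
    return decode(_random_sequence(rng, length))


def build_host_genome(
    config: SimConfig, seed: int
) -> tuple[str, list[tuple[GenomicInterval, str]]]:
    """Random host genome with the UL/Rep10/Rep100 units placed at random
    non-overlapping positions. Deterministic given the seed; errors when the
    repeats cannot be placed without overlap."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    unit = config.repeat_unit_length
    total_units = sum(REPEAT_CLASSES.values())
    if config.genome_length < total_units * unit * 2:
        raise ValueError(
            "genome too small to place repeats without overlap; "
            f"need at least {total_units * unit * 2} bp"
        )
    genome = _random_sequence(rng, config.genome_length)
    units = {name: _random_sequence(rng, unit) for name in REPEAT_CLASSES}
    placements: list[tuple[GenomicInterval, str]] = []
    occupied: list[tuple[int, int]] = []
    margin = config.insert_margin + 50
    for name, copies in REPEAT_CLASSES.items():
        for copy_i in range(copies):
            for attempt in range(1000):
                start = int(rng.integers(margin, config.genome_length - unit - margin))
                if all(start + unit + margin <= s or e + margin <= start for s, e in occupied):
                    break
            else:
                raise ValueError("cannot place repeats without overlap; enlarge the genome")
            occupied.append((start, start + unit))
            copy_seq = units[name].copy()
            if config.repeat_divergence > 0:
                mask = rng.random(unit) < config.repeat_divergence
                shift = rng.integers(1, 4, size=int(mask.sum()))
                copy_seq[mask] = (copy_seq[mask] + shift) % 4
            genome[start : start + unit] = copy_seq
            placements.append(
                (GenomicInterval(HOST_REF, start, start + unit), f"{name}_{copy_i}")
            )
    placements.sort(key=lambda p: p[0])
    return decode(genome), placements


def insert_viral_fragment(
    host_genome: str,
    placements: Sequence[tuple[GenomicInterval, str]],
    viral_source: str,
    config: SimConfig,
    seed: int,
    sample_id: str = "carrier",
) -> tuple[str, SimTruth]:
    """Splice a contiguous viral fragment into one random copy of the chosen
    repeat class; the truth record keeps exact coordinates."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    if config.insert_length > len(viral_source):
        raise ValueError("insert_length exceeds the viral source length")
    candidates = [p for p in placements if p[1].startswith(config.insert_class + "_")]
    if not candidates:
        raise ValueError(f"no {config.insert_class} copy in the annotation")
    copy_iv, _ = candidates[int(rng.integers(len(candidates)))]
    point = int(rng.integers(copy_iv.start + config.insert_margin,
                             copy_iv.end - config.insert_margin))
    v_start = int(rng.integers(0, len(viral_source) - config.insert_length + 1))
    fragment = viral_source[v_start : v_start + config.insert_length]
    modified = host_genome[:point] + fragment + host_genome[point:]
    truth = SimTruth(
        sample_id=sample_id,
        carrier=True,
        insertion_point=point,
        insertion_interval=GenomicInterval(HOST_REF, point, point + config.insert_length),
        locus_class=config.insert_class,
        insert_length=config.insert_length,
        viral_span=GenomicInterval(VIRUS_REF, v_start, v_start + config.insert_length),
        copy_interval=copy_iv,
    )
    return modified, truth


def simulate_reads(
    genome: str,
    config: SimConfig,
    seed: int,
    coverage: Optional[float] = None,
    id_prefix: str = "r",
) -> ReadSet:
    """Uniform paired-read sampling in the style of a short-read simulator:
    FR orientation, Gaussian fragment-length jitter, substitution errors.

    Pair count is ceil(coverage * genome_length / (2 * read_length)).
    """
    cov = config.coverage if coverage is None else coverage
    if cov <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    g = encode(genome)
    L = g.shape[0]
    rl = config.read_length
    n_pairs = math.ceil(cov * L / (2 * rl))
    frag = np.rint(rng.normal(config.fragment_length, config.fragment_sd, n_pairs)).astype(np.int32)
    frag = np.clip(frag, rl, min(L, 2 * config.fragment_length))
    starts = (rng.random(n_pairs) * (L - frag)).astype(np.int32)
    idx1 = starts[:, None] + np.arange(rl, dtype=np.int32)[None, :]
    r1 = g[idx1]
    ends = starts + frag
    idx2 = ends[:, None] - np.arange(rl, 0, -1, dtype=np.int32)[None, :]
    r2_fwd = g[idx2]
    # mate 2 is the reverse-complement of the fragment end
    r2 = r2_fwd[:, ::-1].copy()
    acgt = r2 < 4
    r2[acgt] = 3 - r2[acgt]
    if config.error_rate > 0:
        total = n_pairs * rl
        for mat in (r1, r2):
            n_err = rng.binomial(total, config.error_rate)
            flat = rng.integers(0, total, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            view = mat.reshape(-1)
            ok = view[flat] < 4
            view[flat[ok]] = (view[flat[ok]] + shift[ok]) % 4
    # half the fragments originate from the minus strand: swap mate roles
    swap = rng.random(n_pairs) < 0.5
    r1_final = np.where(swap[:, None], r2, r1)
    r2_final = np.where(swap[:, None], r1, r2)
    ids = [f"{id_prefix}{i:07d}" for i in range(n_pairs)]
    return ReadSet(ids=ids, r1=r1_final, r2=r2_final)


def make_pool(
    carrier_genome: str,
    reference_genome: str,
    config: SimConfig,
    seed: int,
    pool_coverage: Optional[float] = None,
) -> ReadSet:
    """Pool of ``config.pool_size`` individuals with exactly one carrier.

    Each individual contributes pool_coverage / pool_size expected coverage;
    non-carriers share the reference genome. Reads are tagged with their
    individual for debugging only.
    """
    size = config.pool_size
    if size < 1:
        raise ValueError("pool_size must be >= 1")
    cov = (config.coverage if pool_coverage is None else pool_coverage)
    per_ind = cov / size
    carrier = simulate_reads(carrier_genome, config, seed * 2 + 1, coverage=per_ind, id_prefix="c")
    carrier.individuals = ["ind0"] * carrier.n_pairs
    if size == 1:
        return carrier
    background = simulate_reads(
        reference_genome, config, seed * 2 + 2, coverage=per_ind * (size - 1), id_prefix="b"
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    labels = rng.integers(1, size, background.n_pairs)
    background.individuals = [f"ind{k}" for k in labels]
    return ReadSet.concat([carrier, background])


# ---------------------------------------------------------------------------
# Chimera scanning


@dataclass
class ScanConfig:
    k: int = 13
    stride: int = 4
    min_kmer_hits: int = 2
    min_viral_span: int = 20
    min_host_identity: float = 0.9
    secondary_band: float = 0.95  # score band for reporting extra host placements
    scoring: Scoring = field(default_factory=lambda: DEFAULT_SCORING)


@dataclass
class ScanResult:
    rows: list[ChimericTableRow]
    host_alignments: dict[str, list[AlignmentRecord]]
    host_index: SeedIndex
    n_candidates: int = 0


def _viral_hit_counts(reads: np.ndarray, viral_kmers: np.ndarray, cfg: ScanConfig) -> np.ndarray:
    """Per-read count of sampled k-mers present in the viral k-mer set.

    The set holds both strands of the viral sequence, so screening the read
    as stored covers reverse-orientation matches too."""
    from ._sw import kmer_hit_counts

    mat = np.ascontiguousarray(reads, dtype=np.uint8)
    return kmer_hit_counts(mat, np.ascontiguousarray(viral_kmers), cfg.k, cfg.stride)


def chimera_scan(
    reads: ReadSet,
    host_genome: str,
    viral_genome: str,
    config: Optional[ScanConfig] = None,
    sample_id: str = ".",
    host_index: Optional[SeedIndex] = None,
) -> ScanResult:
    """Emit chimeric pairs and host-side alignments for a read set.

    A pair is chimeric when one mate's best alignment is to the host (full
    read identity >= 0.9) and the other mate's best alignment is to the
    virus with an aligned viral span >= 20 nt. The host mate's near-best
    placements (every repeat copy of an exact repeat) are all reported, the
    best as primary and the rest as secondary.
    """
    cfg = config or ScanConfig()
    if host_index is None:
        host_index = build_seed_index(host_genome, cfg.k)
    viral_kmers = np.unique(rolling_viral_kmers(viral_genome, cfg.k))
    host_codes = encode(host_genome)
    viral_codes = encode(viral_genome)
    virus_index = build_seed_index(viral_genome, cfg.k)

    hits1 = _viral_hit_counts(reads.r1, viral_kmers, cfg)
    hits2 = _viral_hit_counts(reads.r2, viral_kmers, cfg)
    candidates = np.nonzero((hits1 >= cfg.min_kmer_hits) | (hits2 >= cfg.min_kmer_hits))[0]

    rows: list[ChimericTableRow] = []
    host_alignments: dict[str, list[AlignmentRecord]] = {}
    for i in candidates:
        pid, s1, s2 = reads.pair_seqs(int(i))
        mates = (s1, s2)
        host_placements: list[list[AlignmentRecord]] = [[], []]
        best_viral: list[Optional[AlignmentRecord]] = [None, None]
        for m, seq in enumerate(mates):
            host_placements[m] = local_align_all(
                seq, host_genome, cfg.scoring, index=host_index,
                ref_name=HOST_REF, read_id=pid, score_band=cfg.secondary_band,
                target_codes=host_codes,
            )
            best_viral[m] = local_align(seq, viral_genome, cfg.scoring, index=virus_index,
                                        ref_name=VIRUS_REF, read_id=pid,
                                        target_codes=viral_codes)
        best_host = [p[0] if p else None for p in host_placements]

        def score(rec: Optional[AlignmentRecord]) -> int:
            return rec.score if rec is not None else 0

        for host_m, viral_m in ((0, 1), (1, 0)):
            h, v = best_host[host_m], best_viral[viral_m]
            if h is None or v is None:
                continue
            if score(h) < score(best_viral[host_m]):
                continue  # the "host" mate looks more viral than host
            if score(v) <= score(best_host[viral_m]):
                continue  # the "viral" mate is better explained by the host
            host_identity = h.n_matches / len(mates[host_m])
            viral_span = v.query_end - v.query_start
            if host_identity < cfg.min_host_identity or viral_span < cfg.min_viral_span:
                continue
            placements = host_placements[host_m]
            rows.append(ChimericTableRow(
                pair_id=pid,
                host_locus=GenomicInterval(HOST_REF, h.start, h.end, h.strand),
                viral_ref=VIRUS_REF,
                viral_span=viral_span,
                host_read_seq=mates[host_m],
                viral_read_seq=mates[viral_m],
                sample_id=sample_id,
            ))
            host_alignments[pid] = placements
            break
    return ScanResult(rows=rows, host_alignments=host_alignments,
                      host_index=host_index, n_candidates=len(candidates))


def rolling_viral_kmers(viral_genome: str, k: int) -> np.ndarray:
    """All k-mer codes of the viral sequence and its reverse complement."""
    from .align import rolling_kmer_codes

    fwd = encode(viral_genome)
    codes = [rolling_kmer_codes(fwd, k), rolling_kmer_codes(revcomp_codes(fwd), k)]
    out = np.concatenate(codes)
    return out[out >= 0]
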