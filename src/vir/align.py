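"""Seed-and-extend local aligner and SAM-flag utilities.

This is the internal short-read aligner used by the refinement, realignment,
read-recruitment and simulation stages. It does exact affine-gap
Smith-Waterman when the problem is small, and restricts the dynamic program
to seed-supported windows of the target when the target is large (a genome).
Scores, CIGARs and flags follow SAM semantics; coordinates are 0-based
half-open throughout.

Default scoring is (match 1, mismatch -4, gap open -6, gap extend -1), chosen
to approximate default short-read aligner behaviour; an alignment is reported
only when score >= 20 and identity >= 0.8 (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _sw
from .intervals import GenomicInterval

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100

MIN_SEED_K = 4

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to codes 0..3, with 4 for N/ambiguous."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def rolling_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Per-position k-mer codes (base-4) of a 1-D code array; -1 where the
    window contains an N. Length is ``len(codes) - k + 1``."""
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for t in range(k):
        out = out * 4 + np.minimum(c[t : t + n], 3)
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    has_n = (cum[k:] - cum[:-k]) > 0
    out[has_n] = -1
    return out


def kmer_codes_matrix(codes: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """K-mer codes for every read in a (n_reads, read_len) code matrix, sampled
    every ``stride`` positions. Windows containing N are -1."""
    n_reads, read_len = codes.shape
    offsets = np.arange(0, read_len - k + 1, stride)
    out = np.zeros((n_reads, offsets.shape[0]), dtype=np.int64)
    for t in range(k):
        np.multiply(out, 4, out=out)
        out += np.minimum(codes[:, offsets + t], 3)
    if (codes >= 4).any():
        bad = (codes >= 4).astype(np.int32)
        cum = np.concatenate([np.zeros((n_reads, 1), np.int32), np.cumsum(bad, axis=1)], axis=1)
        has_n = (cum[:, offsets + k] - cum[:, offsets]) > 0
        out[has_n] = -1
    return out


@dataclass
class SeedIndex:
    """Exact k-mer index of one reference sequence.

    Stored as parallel arrays sorted by k-mer code; lookups are binary
    searches, so the index behaves as a map from k-mer to sorted positions.
    """

    k: int
    ref_length: int
    codes: np.ndarray  # sorted k-mer codes, int64
    starts: np.ndarray  # reference positions, grouped by code, position-sorted

    def lookup_code(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.starts[lo:hi]

    def positions(self, kmer: str) -> list[int]:
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != k={self.k}")
        code = rolling_kmer_codes(encode(kmer), self.k)
        if code.shape[0] == 0 or code[0] < 0:
            return []
        return sorted(self.lookup_code(int(code[0])).tolist())

    def lookup_many(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_offset, target_position) seed hits for an array of
        per-offset query k-mer codes (-1 entries are skipped)."""
        los = np.searchsorted(self.codes, query_codes, side="left")
        his = np.searchsorted(self.codes, query_codes, side="right")
        counts = np.where(query_codes >= 0, his - los, 0)
        hot = np.nonzero(counts)[0]
        if hot.shape[0] == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        q_offs = np.repeat(hot, counts[hot])
        t_pos = np.concatenate([self.starts[los[o] : his[o]] for o in hot])
        return q_offs.astype(np.int64), t_pos.astype(np.int64)


def build_seed_index(reference: str, k: int = 13) -> SeedIndex:
    """Index every k-mer of ``reference`` that contains no N. Deterministic."""
    if k < MIN_SEED_K:
        raise ValueError(f"seed length k={k} is below the minimum {MIN_SEED_K}")
    if k > len(reference):
        raise ValueError(f"seed length k={k} exceeds reference length {len(reference)}")
    codes = rolling_kmer_codes(encode(reference), k)
    valid = codes >= 0
    kmer_codes = codes[valid]
    positions = np.nonzero(valid)[0].astype(np.int64)
    order = np.lexsort((positions, kmer_codes))
    return SeedIndex(k=k, ref_length=len(reference), codes=kmer_codes[order], starts=positions[order])


@dataclass
class Scoring:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_score: int = 20
    min_identity: float = 0.8


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentRecord:
    """One local alignment of a read against a reference, SAM-flavoured.

    ``cigar`` uses ops M/I/D/S; soft clips are the unaligned query ends, given
    in the orientation the read would be stored in a SAM record (i.e. for a
    '-' strand alignment the CIGAR describes the reverse-complemented read).
    Invariants: sum(M, I, S) == read length; end - start == sum(M, D).
    """

    read_id: str
    ref_name: str
    start: int
    end: int
    strand: str
    flag: int
    cigar: list[tuple[str, int]]
    score: int
    identity: float
    is_secondary: bool = False
    query_start: int = 0  # aligned span on the (oriented) query
    query_end: int = 0
    n_matches: int = 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.ref_name, self.start, self.end, self.strand)

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "I", "S"))

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0


def _ops_to_cigar(ops: Sequence[str], qstart: int, qend: int, qlen: int) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    if qstart > 0:
        cigar.append(("S", qstart))
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    if qlen - qend > 0:
        cigar.append(("S", qlen - qend))
    return cigar


def _align_window(
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    t_offset: int,
    strand: str,
    scoring: Scoring,
    ref_name: str,
    read_id: str,
) -> Optional[AlignmentRecord]:
    score, bi, bj, ptr = _sw.sw_affine(
        q_codes, t_codes, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score <= 0 or score < scoring.min_score:
        return None
    ops, matches, qstart, tstart = _sw.traceback(q_codes, t_codes, ptr, int(bi), int(bj))
    if not ops:
        return None
    identity = matches / len(ops)
    rec = AlignmentRecord(
        read_id=read_id,
        ref_name=ref_name,
        start=t_offset + tstart,
        end=t_offset + int(bj),
        strand=strand,
        flag=FLAG_REVERSE if strand == "-" else 0,
        cigar=_ops_to_cigar(ops, qstart, int(bi), q_codes.shape[0]),
        score=int(score),
        identity=identity,
        query_start=qstart,
        query_end=int(bi),
        n_matches=matches,
    )
    return rec


def _seed_windows(
    q_codes: np.ndarray, index: SeedIndex, band: int = 48, min_hits: int = 2
) -> list[tuple[int, int]]:
    """Candidate target windows from seed hits, as merged (start, end) spans.

    Diagonal clusters supported by fewer than ``min_hits`` seeds are noise at
    genome scale and are skipped (the direct-DP small-problem path is exact
    and does not go through seeding).
    """
    qk = rolling_kmer_codes(q_codes, index.k)
    q_offs, t_pos = index.lookup_many(qk)
    if q_offs.shape[0] == 0:
        return []
    diags = t_pos - q_offs
    order = np.argsort(diags, kind="stable")
    diags = diags[order]
    qlen = q_codes.shape[0]
    windows: list[tuple[int, int]] = []
    lo = 0
    for i in range(1, diags.shape[0] + 1):
        if i == diags.shape[0] or diags[i] - diags[i - 1] > band:
            if i - lo >= min_hits:
                dmin, dmax = int(diags[lo]), int(diags[i - 1])
                start = max(0, dmin - band)
                end = min(index.ref_length, dmax + qlen + band)
                windows.append((start, end))
            lo = i
    windows.sort()
    merged: list[tuple[int, int]] = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


def _passes(rec: AlignmentRecord, scoring: Scoring) -> bool:
    return rec.score >= scoring.min_score and rec.identity >= scoring.min_identity


def _candidates(
    query: str,
    target: str,
    scoring: Scoring,
    index: Optional[SeedIndex],
    ref_name: str,
    read_id: str,
    max_dp_cells: int,
    target_codes: Optional[np.ndarray] = None,
) -> list[AlignmentRecord]:
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    t_codes = target_codes if target_codes is not None else encode(target)
    fwd = encode(query)
    rev = revcomp_codes(fwd)
    recs: list[AlignmentRecord] = []
    small = len(query) * len(target) <= max_dp_cells
    if small and index is None:
        for strand, q in (("+", fwd), ("-", rev)):
            rec = _align_window(q, t_codes, 0, strand, scoring, ref_name, read_id)
            if rec is not None and _passes(rec, scoring):
                recs.append(rec)
        return recs
    idx = index if index is not None else build_seed_index(target, k=13)
    for strand, q in (("+", fwd), ("-", rev)):
        for wstart, wend in _seed_windows(q, idx):
            rec = _align_window(q, t_codes[wstart:wend], wstart, strand, scoring, ref_name, read_id)
            if rec is not None and _passes(rec, scoring):
                recs.append(rec)
    return recs


def local_align(
    query: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    index: Optional[SeedIndex] = None,
    ref_name: str = "target",
    read_id: str = "query",
    max_dp_cells: int = 2_000_000,
    target_codes: Optional[np.ndarray] = None,
) -> Optional[AlignmentRecord]:
    """Best local alignment of ``query`` against ``target`` on either strand.

    Returns None when the best alignment scores below ``scoring.min_score`` or
    falls under ``scoring.min_identity``. Ties are broken in favour of the
    '+' strand, then the smallest target start.
    """
    recs = _candidates(query, target, scoring, index, ref_name, read_id, max_dp_cells, target_codes)
    if not recs:
        return None
    return min(recs, key=lambda r: (-r.score, r.strand != "+", r.start))


def local_align_all(
    query: str,
    target: str,
    scoring: Scoring = DEFAULT_SCORING,
    *,
    index: Optional[SeedIndex] = None,
    ref_name: str = "target",
    read_id: str = "query",
    max_dp_cells: int = 2_000_000,
    score_band: float = 0.95,
    target_codes: Optional[np.ndarray] = None,
) -> list[AlignmentRecord]:
    """All near-best placements of ``query`` (for multi-copy references).

    Placements within ``score_band`` of the best score are kept, overlapping
    duplicates suppressed, the best marked primary and the rest secondary.
    Sorted best-first with the same tie-break as :func:`local_align`.
    """
    recs = _candidates(query, target, scoring, index, ref_name, read_id, max_dp_cells, target_codes)
    if not recs:
        return []
    recs.sort(key=lambda r: (-r.score, r.strand != "+", r.start))
    best = recs[0].score
    kept: list[AlignmentRecord] = []
    for rec in recs:
        if rec.score < score_band * best:
            continue
        if any(k.start < rec.end and rec.start < k.end for k in kept):
            continue
        kept.append(rec)
    for i, rec in enumerate(kept):
        rec.is_secondary = i > 0
        if rec.is_secondary:
            rec.flag |= FLAG_SECONDARY
    return kept


def classify_pair_flags(
    host_aln: Optional[AlignmentRecord],
    mate_aln: Optional[AlignmentRecord],
    read_order: str = "first",
) -> tuple[int, int]:
    """Compose the SAM flag pair for a read and its mate.

    ``read_order`` is the order of the first argument's read in the pair.
    An unmapped read inherits its mapped mate's strand bit (the convention
    aligners use when placing an unmapped mate), which is what produces the
    canonical right-end pair (73, 133) and left-end pair (185, 117).
    """
    if host_aln is None and mate_aln is None:
        raise ValueError("at least one of the two alignments must be present")
    if read_order not in ("first", "second"):
        raise ValueError("read_order must be 'first' or 'second'")

    def one(me: Optional[AlignmentRecord], other: Optional[AlignmentRecord], first: bool) -> int:
        flag = FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
        me_rev = (me.strand == "-") if me is not None else (other is not None and other.strand == "-")
        other_rev = (other.strand == "-") if other is not None else me_rev
        if me is None:
            flag |= FLAG_UNMAPPED
        if other is None:
            flag |= FLAG_MATE_UNMAPPED
        if me_rev:
            flag |= FLAG_REVERSE
        if other_rev:
            flag |= FLAG_MATE_REVERSE
        return flag

    first = read_order == "first"
    return one(host_aln, mate_aln, first), one(mate_aln, host_aln, not first)
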