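"""Readers and writers for the formats the pipeline touches.

SAM is read and written through pysam; FASTA random access uses a samtools
faidx index (built on demand). Chimeric-pair tables and reports are TSV via
pandas. Internally everything is 0-based half-open; SAM positions are
converted at this boundary and BED shares the internal convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .align import AlignmentRecord
from .intervals import GenomicInterval

VALID_BASES = set("ACGTN")
SENTINEL = "."


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ChimericTableRow:
    """One chimeric read pair: a host-mapped read plus its virus-mapped mate."""

    pair_id: str
    host_locus: GenomicInterval
    viral_ref: str
    viral_span: int
    host_read_seq: str
    viral_read_seq: str
    sample_id: str = SENTINEL

    def __post_init__(self) -> None:
        for name in ("host_read_seq", "viral_read_seq"):
            seq = getattr(self, name)
            if set(seq) - VALID_BASES:
                raise FormatError(f"{name} of pair {self.pair_id} has non-ACGTN characters")
        if not (0 <= self.viral_span <= len(self.viral_read_seq)):
            raise FormatError(
                f"viral_span {self.viral_span} of pair {self.pair_id} outside "
                f"[0, {len(self.viral_read_seq)}]"
            )


@dataclass(frozen=True)
class ChimericDialect:
    """Column-name map so tables from any upstream chimera caller can be read."""

    pair_id: str = "pair_id"
    sample_id: str = "sample_id"
    host_ref: str = "host_ref"
    host_start: str = "host_start"
    host_end: str = "host_end"
    host_strand: str = "host_strand"
    viral_ref: str = "viral_ref"
    viral_span: str = "viral_span"
    host_read_seq: str = "host_read_seq"
    viral_read_seq: str = "viral_read_seq"

    OPTIONAL = ("sample_id", "host_strand")


DEFAULT_DIALECT = ChimericDialect()


def read_chimeric_table(path, dialect: ChimericDialect = DEFAULT_DIALECT) -> list[ChimericTableRow]:
    """Read a TSV of chimeric pairs; unknown columns are ignored, optional
    columns are filled with a sentinel, missing required columns raise."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {f.name: getattr(dialect, f.name) for f in dc_fields(dialect)}
    missing = [col for name, col in required.items() if name not in dialect.OPTIONAL and col not in df.columns]
    if missing:
        raise FormatError(f"chimeric table {path} is missing required columns: {missing}")
    rows: list[ChimericTableRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        def get(name: str, default: str = SENTINEL) -> str:
            col = required[name]
            return rec.get(col, default)

        try:
            span = int(get("viral_span"))
            start = int(get("host_start"))
            end = int(get("host_end"))
        except ValueError as exc:
            raise FormatError(f"non-numeric field in chimeric table row {i + 1}: {exc}") from exc
        strand = get("host_strand", "unknown")
        rows.append(
            ChimericTableRow(
                pair_id=get("pair_id"),
                host_locus=GenomicInterval(get("host_ref"), start, end,
                                           strand if strand in ("+", "-") else "unknown"),
                viral_ref=get("viral_ref"),
                viral_span=span,
                host_read_seq=get("host_read_seq").upper(),
                viral_read_seq=get("viral_read_seq").upper(),
                sample_id=get("sample_id"),
            )
        )
    return rows


def write_chimeric_table(rows: Iterable[ChimericTableRow], path,
                         dialect: ChimericDialect = DEFAULT_DIALECT) -> None:
    records = []
    for r in rows:
        records.append({
            dialect.pair_id: r.pair_id,
            dialect.sample_id: r.sample_id,
            dialect.host_ref: r.host_locus.ref_name,
            dialect.host_start: r.host_locus.start,
            dialect.host_end: r.host_locus.end,
            dialect.host_strand: r.host_locus.strand,
            dialect.viral_ref: r.viral_ref,
            dialect.viral_span: r.viral_span,
            dialect.host_read_seq: r.host_read_seq,
            dialect.viral_read_seq: r.viral_read_seq,
        })
    cols = [getattr(dialect, f.name) for f in dc_fields(dialect)]
    pd.DataFrame(records, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM


def read_alignments(path) -> Iterator[AlignmentRecord]:
    """Stream every record of a SAM file (secondary/supplementary included).

    Coordinates come out 0-based half-open; flags are preserved verbatim.
    Unmapped records are skipped (they carry no interval). A missing header
    or a malformed record raises :class:`FormatError` naming the position.
    """
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: missing or invalid SAM header ({exc})") from exc
    if not sam.header.to_dict():
        raise FormatError(f"{path}: missing SAM header")
    n = 0
    try:
        for rec in sam:
            n += 1
            if rec.is_unmapped or rec.reference_id < 0:
                continue
            cigar = []
            for op, length in rec.cigartuples or []:
                sym = "MIDNSHP=XB"[op]
                if sym in ("=", "X"):
                    sym = "M"
                if sym in ("M", "I", "D", "S"):
                    cigar.append((sym, length))
            yield AlignmentRecord(
                read_id=rec.query_name,
                ref_name=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                flag=rec.flag,
                cigar=cigar,
                score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                identity=float(rec.get_tag("XI")) if rec.has_tag("XI") else 1.0,
                is_secondary=rec.is_secondary,
            )
    except (ValueError, OSError, NotImplementedError) as exc:
        raise FormatError(f"{path}: malformed SAM record at body line {n + 1} ({exc})") from exc
    finally:
        sam.close()


def write_sam(
    path,
    records: Iterable[tuple[AlignmentRecord, Optional[str]]],
    references: Sequence[tuple[str, int]],
) -> None:
    """Write (record, sequence) pairs as SAM. ``sequence`` may be None ('*')."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec, seq in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = rec.flag
            if rec.ref_name in ref_ids and not (rec.flag & 0x4):
                a.reference_id = ref_ids[rec.ref_name]
                a.reference_start = rec.start
                a.mapping_quality = 60 if not rec.is_secondary else 0
                if rec.cigar:
                    a.cigarstring = rec.cigar_string()
            else:
                a.reference_id = -1
            if seq:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("AS", rec.score)
            out.write(a)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def extract_region_sequence(fasta: Union[str, os.PathLike, Mapping[str, str]],
                            region: GenomicInterval) -> str:
    """Uppercase sequence of ``region``; errors on unknown reference or
    out-of-bounds coordinates. ``fasta`` is a path (faidx-indexed on demand)
    or an in-memory name->sequence mapping."""
    if isinstance(fasta, Mapping):
        if region.ref_name not in fasta:
            raise FormatError(f"unknown reference {region.ref_name!r}")
        seq = fasta[region.ref_name]
        if region.end > len(seq):
            raise FormatError(
                f"region {region} out of bounds for {region.ref_name} (length {len(seq)})")
        return seq[region.start : region.end].upper()
    path = str(fasta)
    if not os.path.exists(path + ".fai"):
        pysam.faidx(path)
    with pysam.FastaFile(path) as fa:
        if region.ref_name not in fa.references:
            raise FormatError(f"unknown reference {region.ref_name!r} in {path}")
        if region.end > fa.get_reference_length(region.ref_name):
            raise FormatError(f"region {region} out of bounds in {path}")
        return fa.fetch(region.ref_name, region.start, region.end).upper()


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            out[entry.name] = entry.sequence.upper()
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (id, seq) pairs with constant 'I' quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    """Read mate FASTQ files into (pair_id, seq1, seq2) triples (file order)."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        out = []
        for e1, e2 in zip(f1, f2):
            rid = e1.name
            for suffix in ("/1", "/2"):
                if rid.endswith(suffix):
                    rid = rid[: -len(suffix)]
            out.append((rid, e1.sequence.upper(), e2.sequence.upper()))
        return out


# ---------------------------------------------------------------------------
# Calls

CALL_COLUMNS = [
    "group_id", "region", "viral_species", "left_support", "right_support",
    "breakpoint_left", "breakpoint_right", "left_consensus", "right_consensus",
    "resolved",
]


def write_calls(calls: Sequence, bed_path, tsv_path) -> None:
    """One BED row per equivalent-region interval, one TSV row per call,
    ordered by (ref, start) of the call's first interval."""
    if calls is None:
        raise ValueError("calls must not be None")
    ordered = sorted(calls, key=lambda c: min((iv.ref_name, iv.start) for iv in c.region))
    with open(bed_path, "w") as bed:
        bed.write("#chrom\tstart\tend\tgroup_id\n")
        for call in ordered:
            for iv in sorted(call.region):
                bed.write(f"{iv.ref_name}\t{iv.start}\t{iv.end}\t{call.group_id}\n")
    rows = []
    for call in ordered:
        rows.append({
            "group_id": call.group_id,
            "region": ";".join(str(iv) for iv in sorted(call.region)),
            "viral_species": call.viral_species,
            "left_support": call.left_support,
            "right_support": call.right_support,
            "breakpoint_left": SENTINEL if call.breakpoint_left is None else call.breakpoint_left,
            "breakpoint_right": SENTINEL if call.breakpoint_right is None else call.breakpoint_right,
            "left_consensus": call.left_consensus or SENTINEL,
            "right_consensus": call.right_consensus or SENTINEL,
            "resolved": call.resolved,
        })
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(tsv_path, sep="\t", index=False)


def read_calls(tsv_path) -> list:
    from .group_align import IntegrationCall  # local import to avoid a cycle
    from .intervals import parse_locus

    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"calls table {tsv_path} missing columns: {missing}")
    calls = []
    for rec in df.to_dict("records"):
        calls.append(IntegrationCall(
            group_id=rec["group_id"],
            region=[parse_locus(tok) for tok in rec["region"].split(";")],
            viral_species=rec["viral_species"],
            left_support=int(rec["left_support"]),
            right_support=int(rec["right_support"]),
            breakpoint_left=None if rec["breakpoint_left"] == SENTINEL else int(rec["breakpoint_left"]),
            breakpoint_right=None if rec["breakpoint_right"] == SENTINEL else int(rec["breakpoint_right"]),
            left_consensus="" if rec["left_consensus"] == SENTINEL else rec["left_consensus"],
            right_consensus="" if rec["right_consensus"] == SENTINEL else rec["right_consensus"],
            resolved=rec["resolved"],
        ))
    return calls


def read_bed_annotations(path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED file into (interval, label) pairs; column 4 is the label."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line with fewer than 3 columns")
            label = parts[3] if len(parts) > 3 else SENTINEL
            out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), label))
    return out


def validate(path) -> str:
    """Light-weight validation used by ``vir io validate``; returns the kind."""
    path = str(path)
    if path.endswith((".sam",)):
        for _ in read_alignments(path):
            pass
        return "sam"
    if path.endswith((".fa", ".fasta")):
        seqs = read_fasta(path)
        if not seqs:
            raise FormatError(f"{path}: no sequences")
        return "fasta"
    if path.endswith((".fq", ".fastq")):
        with pysam.FastxFile(path) as fx:
            for _ in fx:
                pass
        return "fastq"
    if path.endswith(".bed"):
        read_bed_annotations(path)
        return "bed"
    if path.endswith((".tsv", ".txt")):
        read_chimeric_table(path)
        return "chimeric-table"
    raise FormatError(f"{path}: unrecognized file type")
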