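"""Extraction and classification of clipped alignment records.

Back-spliced junction (BSJ) reads align to the linear reference as two (or
three) segments in reversed genomic order, so a split-read aligner reports
them as soft/hard-clipped records.  Records whose CIGAR is ``xS|H yM`` belong
to the *left-junction cluster* (the matched part starts at the putative
circRNA acceptor, the clipped part is donor-side sequence); ``xM yS|H``
records belong to the *right-junction cluster* (matched part ends at the
donor).  Records clipped on both ends arise from circles shorter than the
read length or from short flanking exons and are members of both clusters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

import pysam

logger = logging.getLogger("circjunction")

_CIGAR_OPS = "MIDNSHP=X"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operators that consume reference bases.
_REF_CONSUMING = frozenset("MDN=X")
# CIGAR operators that consume read (query) bases.
_READ_CONSUMING = frozenset("MIS=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CigarOp:
    """A single CIGAR operation (operator code + run length in bases)."""

    code: str
    length: int

    def __post_init__(self) -> None:
        if self.code not in _CIGAR_OPS:
            raise ValueError(f"invalid CIGAR operator {self.code!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR length must be >= 1, got {self.length}")

    def __str__(self) -> str:
        return f"{self.length}{self.code}"


class ClusterAssignment(Enum):
    """Which junction cluster(s) a clipped record belongs to."""

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BOTH = "BOTH"
    NONE = "NONE"


@dataclass
class ClippedRead:
    """One clipped alignment record, the unit of downstream pairing.

    Coordinates are SAM 1-based inclusive.  ``sequence`` is the full read in
    reference orientation (reconstructed from the primary record when the
    aligner hard-clipped it).  ``left_clip``/``right_clip`` are clip lengths
    in reference orientation, regardless of the original read orientation.
    """

    read_id: str
    mate_index: int  # 1 or 2
    chrom: str
    pos: int  # leftmost mapped reference coordinate, 1-based
    strand: str  # '+' or '-'
    mapq: int
    cigar: list[CigarOp]
    sequence: str
    left_clip: int
    right_clip: int
    match_start: int
    match_end: int
    mate_chrom: str | None
    mate_pos: int | None  # 1-based
    mate_strand: str | None
    cluster: ClusterAssignment = ClusterAssignment.NONE

    @property
    def key(self) -> tuple[str, int]:
        """Identity of the sequenced read (one end of a pair)."""
        return (self.read_id, self.mate_index)


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a SAM CIGAR string into a list of :class:`CigarOp`.

    The unmapped sentinel ``"*"`` yields an empty list.  Raises
    ``ValueError`` naming the offending token on malformed input.
    """
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed CIGAR near {text[pos:m.start()]!r} in {text!r}")
        ops.append(CigarOp(m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ValueError(f"malformed CIGAR near {text[pos:]!r} in {text!r}")
    return ops


def cigar_to_string(ops: Iterable[CigarOp]) -> str:
    return "".join(str(op) for op in ops) or "*"


def _end_clips(cigar: list[CigarOp]) -> tuple[int, int]:
    """(leading, trailing) clip lengths; S and H are equivalent."""
    leading = trailing = 0
    i = 0
    while i < len(cigar) and cigar[i].code in "SH":
        leading += cigar[i].length
        i += 1
    j = len(cigar) - 1
    while j >= i and cigar[j].code in "SH":
        trailing += cigar[j].length
        j -= 1
    return leading, trailing


def classify_alignment(cigar: list[CigarOp], min_clip: int) -> ClusterAssignment:
    """Assign a record to junction cluster(s) from its CIGAR shape.

    LEFT when only the 5'-side (reference orientation) clip reaches
    ``min_clip``; RIGHT for the 3'-side; BOTH when both ends are clipped at
    least that much (three-segment styles); NONE otherwise.
    """
    if not cigar:
        raise ValueError("cannot classify an empty CIGAR")
    leading, trailing = _end_clips(cigar)
    left = leading >= min_clip
    right = trailing >= min_clip
    if left and right:
        return ClusterAssignment.BOTH
    if left:
        return ClusterAssignment.LEFT
    if right:
        return ClusterAssignment.RIGHT
    return ClusterAssignment.NONE


def _matched_span(pos: int, cigar: list[CigarOp]) -> tuple[int, int]:
    """1-based inclusive reference span covered by M/=/X/D/N operations."""
    ref_len = sum(op.length for op in cigar if op.code in _REF_CONSUMING)
    return pos, pos + ref_len - 1


@dataclass
class IngestStats:
    """Counters logged by :func:`extract_clipped_reads`."""

    records: int = 0
    skipped_flags: int = 0
    unrecovered_hard_clips: int = 0
    left: int = 0
    right: int = 0


def _record_to_clipped(
    rec: pysam.AlignedSegment,
    cigar: list[CigarOp],
    sequence: str,
) -> ClippedRead:
    leading, trailing = _end_clips(cigar)
    match_start, match_end = _matched_span(rec.reference_start + 1, cigar)
    mate_mapped = not rec.mate_is_unmapped and rec.next_reference_name is not None
    return ClippedRead(
        read_id=rec.query_name,
        mate_index=2 if rec.is_read2 else 1,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        cigar=cigar,
        sequence=sequence,
        left_clip=leading,
        right_clip=trailing,
        match_start=match_start,
        match_end=match_end,
        mate_chrom=rec.next_reference_name if mate_mapped else None,
        mate_pos=rec.next_reference_start + 1 if mate_mapped else None,
        mate_strand=("-" if rec.mate_is_reverse else "+") if mate_mapped else None,
    )


def extract_clipped_reads(
    path: str,
    min_clip: int = 10,
    min_mapq: int = 1,
) -> tuple[list[ClippedRead], list[ClippedRead], IngestStats]:
    """Scan a SAM/BAM file and build the left- and right-junction clusters.

    Every mapped record (primary, secondary or supplementary; duplicates and
    QC-fail records are skipped) with mapping quality ``>= min_mapq`` whose
    CIGAR classification is LEFT/RIGHT/BOTH contributes one
    :class:`ClippedRead`; BOTH records contribute to both clusters.  Each end
    of a pair and every alignment record of a multi-mapped read is considered
    independently.  Hard-clipped records have their sequence recovered from
    the same read's primary record when one was seen; otherwise the record is
    dropped and counted.
    """
    stats = IngestStats()
    left: list[ClippedRead] = []
    right: list[ClippedRead] = []
    # (read_id, mate_index) -> (sequence in reference orientation, strand)
    primary_seqs: dict[tuple[str, int], tuple[str, str]] = {}
    pending_hard: list[tuple[pysam.AlignedSegment, list[CigarOp]]] = []

    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        if not fh.header.references:
            raise OSError(f"{path}: SAM/BAM header with reference sequences required")
        for rec in fh:
            if rec.is_unmapped:
                # FLAG 0x4 records carry no position; they are not the
                # "unmapped reads" of the split-read sense and are ignored.
                continue
            if rec.is_duplicate or rec.is_qcfail:
                stats.skipped_flags += 1
                continue
            stats.records += 1
            cigar = parse_cigar(rec.cigarstring or "*")
            if not cigar:
                continue
            has_hard = any(op.code == "H" for op in cigar)
            if not has_hard and rec.query_sequence and not rec.is_secondary and not rec.is_supplementary:
                key = (rec.query_name, 2 if rec.is_read2 else 1)
                primary_seqs.setdefault(key, (rec.query_sequence, "-" if rec.is_reverse else "+"))
            if rec.mapping_quality < min_mapq:
                continue
            if classify_alignment(cigar, min_clip) is ClusterAssignment.NONE:
                continue
            if has_hard or not rec.query_sequence:
                pending_hard.append((rec, cigar))
                continue
            _place(_record_to_clipped(rec, cigar, rec.query_sequence), min_clip, left, right)

    for rec, cigar in pending_hard:
        key = (rec.query_name, 2 if rec.is_read2 else 1)
        found = primary_seqs.get(key)
        if found is None:
            stats.unrecovered_hard_clips += 1
            continue
        seq, primary_strand = found
        strand = "-" if rec.is_reverse else "+"
        if strand != primary_strand:
            seq = reverse_complement(seq)
        _place(_record_to_clipped(rec, cigar, seq), min_clip, left, right)

    stats.left, stats.right = len(left), len(right)
    if stats.unrecovered_hard_clips:
        logger.info(
            "dropped %d hard-clipped records without a recoverable sequence",
            stats.unrecovered_hard_clips,
        )
    logger.info(
        "ingest: %d records scanned, %d left-cluster, %d right-cluster reads",
        stats.records, stats.left, stats.right,
    )
    return left, right, stats


def _place(
    read: ClippedRead,
    min_clip: int,
    left: list[ClippedRead],
    right: list[ClippedRead],
) -> None:
    cluster = classify_alignment(read.cigar, min_clip)
    read.cluster = cluster
    if cluster in (ClusterAssignment.LEFT, ClusterAssignment.BOTH):
        left.append(read)
    if cluster in (ClusterAssignment.RIGHT, ClusterAssignment.BOTH):
        right.append(replace(read) if cluster is ClusterAssignment.BOTH else read)
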