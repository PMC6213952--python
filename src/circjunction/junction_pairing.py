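"""Paired-end-mapping (PEM) filtering and candidate pair enumeration.

A clipped read only evidences a circRNA when its mate maps inside the
putative circle: fragments of a circular transcript live on the circle, so
both reads of a pair must fall within the genomic interval
``[acceptor, donor]``.  Candidate back-spliced junctions are enumerated as
left-cluster x right-cluster read pairs subject to four restrictions: same
chromosome, left read upstream of the right read, a bounded genomic span,
and adequate mapping quality; the mate-placement test is evaluated against
the pair's inferred span.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterator

from .alignment_ingest import ClippedRead


@dataclass(frozen=True)
class Junction:
    """A putative back-spliced junction.

    ``acceptor`` is the genomic start of the circle (the 3' splice acceptor,
    left boundary); ``donor`` its genomic end (5' splice donor, right
    boundary).  1-based inclusive.
    """

    chrom: str
    acceptor: int
    donor: int

    def __post_init__(self) -> None:
        if self.acceptor > self.donor:
            raise ValueError(f"acceptor {self.acceptor} > donor {self.donor}")

    @property
    def span(self) -> int:
        return self.donor - self.acceptor + 1

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.acceptor}|{self.donor}"


@dataclass
class CandidatePair:
    """A left-cluster read and a right-cluster read with their inferred junction."""

    left: ClippedRead
    right: ClippedRead
    junction: Junction


def infer_junction(left: ClippedRead, right: ClippedRead) -> Junction:
    """Junction implied by a pair: acceptor at the left read's matched start,
    donor at the right read's matched end."""
    if left.chrom != right.chrom:
        raise ValueError("junction requires both reads on one chromosome")
    return Junction(left.chrom, left.match_start, right.match_end)


def mate_consistent(
    read: ClippedRead,
    span: tuple[int, int],
    strict_orientation: bool = False,
    library_layout: str = "fr",
) -> bool:
    """PEM test: does the read's mate support the putative circle ``span``?

    Requires the mate on the same chromosome, its position inside
    ``[acceptor, donor]`` (inclusive boundaries), and opposite read/mate
    orientations (same-direction pairs are filtered).  With
    ``strict_orientation`` the orientation is additionally pinned to the
    literal rule: LEFT-cluster read '+' with '-' mate, RIGHT-cluster read
    '-' with '+' mate (reversed for an RF library).
    """
    if read.mate_chrom is None or read.mate_pos is None or read.mate_strand is None:
        return False
    if read.mate_chrom != read.chrom:
        return False
    acceptor, donor = span
    if not acceptor <= read.mate_pos <= donor:
        return False
    if read.strand == read.mate_strand:
        return False
    if strict_orientation:
        from .alignment_ingest import ClusterAssignment

        forward = "+" if library_layout == "fr" else "-"
        reverse = "-" if library_layout == "fr" else "+"
        if read.cluster is ClusterAssignment.LEFT and read.strand != forward:
            return False
        if read.cluster is ClusterAssignment.RIGHT and read.strand != reverse:
            return False
    return True


def pair_admissible(
    left: ClippedRead,
    right: ClippedRead,
    max_span: int,
    min_mapq_pair: int,
    strict_orientation: bool = False,
    library_layout: str = "fr",
) -> CandidatePair | None:
    """Apply the four pairing restrictions to one (left, right) combination."""
    if left.chrom != right.chrom:
        return None
    if left.key == right.key:
        # a read never pairs with itself (BOTH-cluster records)
        return None
    if left.match_start > right.match_end:
        return None
    junction = Junction(left.chrom, left.match_start, right.match_end)
    if junction.span > max_span:
        return None
    if left.mapq < min_mapq_pair or right.mapq < min_mapq_pair:
        return None
    span = (junction.acceptor, junction.donor)
    if not mate_consistent(left, span, strict_orientation, library_layout):
        return None
    if not mate_consistent(right, span, strict_orientation, library_layout):
        return None
    return CandidatePair(left, right, junction)


def enumerate_pairs(
    left_cluster: list[ClippedRead],
    right_cluster: list[ClippedRead],
    max_span: int = 200_000,
    min_mapq_pair: int = 10,
    strict_orientation: bool = False,
    library_layout: str = "fr",
) -> Iterator[CandidatePair]:
    """Yield every admissible left x right candidate pair.

    Uses a per-chromosome sorted sliding window of width ``max_span`` over
    left-read start positions; the result equals the brute-force cross
    product filtered by the restrictions, in deterministic order (sorted by
    junction, then read identities).
    """
    by_chrom: dict[str, list[ClippedRead]] = {}
    for read in left_cluster:
        by_chrom.setdefault(read.chrom, []).append(read)
    starts_by_chrom: dict[str, list[int]] = {}
    for chrom, reads in by_chrom.items():
        reads.sort(key=lambda r: (r.match_start, r.key))
        starts_by_chrom[chrom] = [r.match_start for r in reads]

    out: list[CandidatePair] = []
    for right in right_cluster:
        lefts = by_chrom.get(right.chrom)
        if not lefts:
            continue
        starts = starts_by_chrom[right.chrom]
        lo = bisect_left(starts, right.match_end - max_span + 1)
        hi = bisect_right(starts, right.match_end)
        for left in lefts[lo:hi]:
            pair = pair_admissible(
                left, right, max_span, min_mapq_pair, strict_orientation, library_layout
            )
            if pair is not None:
                out.append(pair)
    out.sort(
        key=lambda p: (
            p.junction.chrom, p.junction.acceptor, p.junction.donor,
            p.left.key, p.right.key,
        )
    )
    yield from out
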