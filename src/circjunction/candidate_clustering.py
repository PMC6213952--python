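"""Junction clustering, final filtering and the detection pipeline.

Accepted BSJ read pairs rarely agree on the exact junction base: sequencing
errors and fortuitously matching bases shift the apparent clip boundary by a
few bases.  Pairs are therefore clustered by single linkage over junction
loci (same chromosome, both boundaries within a tolerance), the modal member
junction is reported, and candidates must finally show at least
``min_side_support`` distinct reads on *each* splice site plus a reliable
mean mapping quality.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .alignment_ingest import ClippedRead, extract_clipped_reads
from .junction_pairing import CandidatePair, Junction, pair_admissible
from .local_similarity import ScoringScheme, accept_pair, mismatch_threshold

logger = logging.getLogger("circjunction")


@dataclass
class DetectionParams:
    """Tunable parameters of the detection pipeline (defaults for ~100 bp reads).

    ``max_mismatch``/``max_gap`` set to None are scaled per pair as
    ceil(0.02 x read length), so shorter reads get proportionally stricter
    thresholds.
    """

    min_clip: int = 10
    min_mapq_ingest: int = 1
    max_span: int = 200_000
    min_mapq_pair: int = 10
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    max_mismatch: int | None = None
    max_gap: int | None = None
    min_overlap: int = 15
    seed_len: int = 12
    tolerance: int = 5
    min_side_support: int = 2
    min_mean_mapq: float = 10.0
    strict_orientation: bool = False
    library_layout: str = "fr"


@dataclass
class CircRNACandidate:
    """A clustered circRNA junction call."""

    junction: Junction
    support_left: int
    support_right: int
    bsj_count: int
    mean_mapq: float
    member_junctions: list[Junction]
    pairs: list[CandidatePair] = field(default_factory=list, repr=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_junctions(pairs: list[CandidatePair], tolerance: int = 5) -> list[CircRNACandidate]:
    """Single-linkage clustering of accepted pairs by junction locus.

    Two junctions link iff they share a chromosome and both |delta acceptor|
    and |delta donor| are within ``tolerance``.  The representative is the
    most frequent member junction (ties to the smallest coordinates); each
    distinct read is counted once per cluster per side.
    """
    if not pairs:
        return []
    juncs = sorted({p.junction for p in pairs}, key=lambda j: (j.chrom, j.acceptor, j.donor))
    index = {j: i for i, j in enumerate(juncs)}
    uf = _UnionFind(len(juncs))
    for i, j1 in enumerate(juncs):
        for j2 in juncs[i + 1:]:
            if j2.chrom != j1.chrom or j2.acceptor - j1.acceptor > tolerance:
                break
            if abs(j2.donor - j1.donor) <= tolerance:
                uf.union(i, index[j2])

    groups: dict[int, list[CandidatePair]] = {}
    for p in pairs:
        groups.setdefault(uf.find(index[p.junction]), []).append(p)

    candidates = []
    for root in sorted(groups):
        members = groups[root]
        freq = Counter(p.junction for p in members)
        top = max(freq.values())
        representative = min(
            (j for j, c in freq.items() if c == top),
            key=lambda j: (j.acceptor, j.donor),
        )
        left_keys = {p.left.key for p in members}
        right_keys = {p.right.key for p in members}
        names = {p.left.read_id for p in members} | {p.right.read_id for p in members}
        records = {(p.left.key, "L"): p.left.mapq for p in members}
        records.update({(p.right.key, "R"): p.right.mapq for p in members})
        candidates.append(
            CircRNACandidate(
                junction=representative,
                support_left=len(left_keys),
                support_right=len(right_keys),
                bsj_count=len(names),
                mean_mapq=sum(records.values()) / len(records),
                member_junctions=sorted(freq, key=lambda j: (j.acceptor, j.donor)),
                pairs=members,
            )
        )
    candidates.sort(key=lambda c: (c.junction.chrom, c.junction.acceptor, c.junction.donor))
    return candidates


def apply_final_filters(
    candidates: list[CircRNACandidate],
    min_side_support: int = 2,
    min_mean_mapq: float = 10.0,
) -> list[CircRNACandidate]:
    """Keep candidates with at least ``min_side_support`` reads on each
    splice site and reliable mean mapping quality."""
    return [
        c for c in candidates
        if c.support_left >= min_side_support
        and c.support_right >= min_side_support
        and c.mean_mapq >= min_mean_mapq
    ]


def _seeded_candidate_pairs(
    left_cluster: list[ClippedRead],
    right_cluster: list[ClippedRead],
    params: DetectionParams,
) -> list[CandidatePair]:
    """Admissible pairs that also share an exact ``seed_len``-mer.

    The seed requirement is lossless whenever the similar region of a
    genuine pair is error-free over ``min_overlap`` columns (it then
    contains an exact ``min_overlap``-mer >= seed_len) and prunes the
    quadratic cross product to near-linear work.
    """
    k = params.seed_len
    index: dict[str, dict[str, list[int]]] = {}
    for idx, read in enumerate(left_cluster):
        chrom_index = index.setdefault(read.chrom, {})
        seq = read.sequence.upper()
        for off in range(len(seq) - k + 1):
            chrom_index.setdefault(seq[off:off + k], []).append(idx)

    pairs: list[CandidatePair] = []
    for right in right_cluster:
        chrom_index = index.get(right.chrom)
        if not chrom_index:
            continue
        seq = right.sequence.upper()
        seen: set[int] = set()
        for off in range(len(seq) - k + 1):
            hits = chrom_index.get(seq[off:off + k])
            if hits:
                seen.update(hits)
        for idx in sorted(seen):
            pair = pair_admissible(
                left_cluster[idx], right,
                params.max_span, params.min_mapq_pair,
                params.strict_orientation, params.library_layout,
            )
            if pair is not None:
                pairs.append(pair)
    pairs.sort(
        key=lambda p: (
            p.junction.chrom, p.junction.acceptor, p.junction.donor,
            p.left.key, p.right.key,
        )
    )
    return pairs


def _pair_thresholds(pair: CandidatePair, params: DetectionParams) -> tuple[int, int]:
    read_len = min(len(pair.left.sequence), len(pair.right.sequence))
    scaled = mismatch_threshold(read_len)
    mm = params.max_mismatch if params.max_mismatch is not None else scaled
    gp = params.max_gap if params.max_gap is not None else scaled
    return mm, gp


def detect_circRNAs(
    sam_path: str,
    params: DetectionParams | None = None,
    workers: int = 1,
) -> list[CircRNACandidate]:
    """Run the four-step detection pipeline on a SAM/BAM file.

    Steps: extract and classify clipped reads; enumerate PEM-consistent
    candidate pairs; accept pairs sharing a junction-spanning local similar
    sequence; cluster junction loci and apply the final support/quality
    filters.  The accepted set is independent of ``workers`` (pairs are
    evaluated by a pure function in any partitioning).
    """
    params = params or DetectionParams()
    left, right, _ = extract_clipped_reads(sam_path, params.min_clip, params.min_mapq_ingest)
    pairs = _seeded_candidate_pairs(left, right, params)
    logger.info("pairing: %d candidate pairs", len(pairs))

    chunks = [pairs[w::workers] for w in range(max(1, workers))]
    accepted: list[CandidatePair] = []
    for chunk in chunks:
        for pair in chunk:
            mm, gp = _pair_thresholds(pair, params)
            if accept_pair(pair, params.scoring, mm, gp, params.min_overlap):
                accepted.append(pair)
    accepted.sort(
        key=lambda p: (
            p.junction.chrom, p.junction.acceptor, p.junction.donor,
            p.left.key, p.right.key,
        )
    )
    logger.info("similarity: %d putative BSJ pairs", len(accepted))

    clustered = cluster_junctions(accepted, params.tolerance)
    final = apply_final_filters(clustered, params.min_side_support, params.min_mean_mapq)
    logger.info("clustering: %d clusters, %d candidates after final filters",
                len(clustered), len(final))
    return final


def write_candidates(candidates: list[CircRNACandidate], path: str, bed_path: str | None = None) -> None:
    """Write the candidate table as TSV (1-based inclusive coordinates) and
    optionally as BED6 (0-based half-open, score = BSJ read count)."""
    header = ["chrom", "start", "end", "bsj_count", "support_left",
              "support_right", "mean_mapq", "circ_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            j = c.junction
            fh.write(
                f"{j.chrom}\t{j.acceptor}\t{j.donor}\t{c.bsj_count}\t"
                f"{c.support_left}\t{c.support_right}\t{c.mean_mapq:.2f}\t{j.circ_id}\n"
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for c in candidates:
                j = c.junction
                fh.write(f"{j.chrom}\t{j.acceptor - 1}\t{j.donor}\t{j.circ_id}\t{c.bsj_count}\t.\n")
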