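"""Synthetic genomes, transcripts and paired-end reads with split alignments.

Desk-scale stand-in for a transcriptome read simulator plus a split-read
aligner: it builds a random genome with non-overlapping gene models, samples
circular transcripts of the hard subtypes (multi-exon, single-exon,
intron-retained, circles shorter than the read length, and circles with a
short flanking exon), sequences linear and circular transcripts as FR
paired-end reads with uniform substitution errors, and emits the alignments
those reads would receive: full-match records for contiguous reads,
soft-clipped records anchored on the longest genomic segment for
junction-crossing reads (plus supplementary records for other segments of at
least ``SUPPLEMENTARY_MIN`` bases, mirroring the minimum seed length of
split-read aligners, which drop shorter splits), and the double-clipped
``xSyMzS`` pattern for reads wrapping a circle shorter than themselves.

All randomness flows from one generator seeded by ``SimConfig.seed`` and is
consumed in a fixed order (genome -> gene models -> circles -> reads ->
errors), so every output is byte-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .alignment_ingest import reverse_complement
from .junction_pairing import Junction

SUPPLEMENTARY_MIN = 19

SUBTYPES = ("multi_exon", "single_exon", "intron_retained", "small", "short_flank")

_DEFAULT_MIX = {
    "multi_exon": 0.40,
    "single_exon": 0.20,
    "intron_retained": 0.15,
    "small": 0.10,
    "short_flank": 0.15,
}


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised."""


@dataclass
class SimConfig:
    """Study conditions of one simulated dataset.

    Depths are fold coverages of the circular / linear transcripts; the
    error rate is a per-base substitution probability; insert sizes are
    drawn from a normal distribution (mean/sd in bases).
    """

    genome_length: int = 500_000
    n_genes: int = 50
    exon_length_range: tuple[int, int] = (30, 350)
    intron_length_range: tuple[int, int] = (100, 600)
    exons_per_gene_range: tuple[int, int] = (3, 8)
    n_circ: int = 30
    subtype_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    depth_circ: float = 10.0
    depth_linear: float = 10.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.01
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_genes < 0 or self.n_circ < 0:
            raise SimulationError("counts and lengths must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.read_len <= 0:
            raise SimulationError("read_len must be positive")
        unknown = set(self.subtype_mix) - set(SUBTYPES)
        if unknown:
            raise SimulationError(f"unknown circRNA subtypes: {sorted(unknown)}")
        if abs(sum(self.subtype_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("subtype_mix proportions must sum to 1")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class TruthRecord:
    """One preset circRNA: identity, genomic blocks and junction."""

    circ_id: str
    junction: Junction
    subtype: str
    blocks: list[tuple[int, int]]  # genomic blocks (exons / merged retained introns)
    circ_length: int
    read_ids: list[str] = field(default_factory=list)


@dataclass
class Transcript:
    name: str
    chrom: str
    blocks: list[tuple[int, int]]
    circular: bool

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)


@dataclass
class SimulatedRead:
    """One sequenced read end, in reference (= transcript) orientation."""

    name: str
    mate_index: int
    strand: str  # orientation of the read as sequenced
    seq_stored: str  # genome-forward sequence, errors applied
    tstart: int  # 0-based start on the (circularised) transcript
    transcript: Transcript


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[str, list[GeneModel]]:
    """I.i.d. uniform ACGT genome plus non-overlapping gene models."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = bases[rng.integers(0, 4, size=config.genome_length)].tobytes().decode("ascii")

    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genome, genes

    elo, ehi = config.exon_length_range
    ilo, ihi = config.intron_length_range
    nlo, nhi = config.exons_per_gene_range
    structures = []
    total = 0
    for _ in range(config.n_genes):
        n_exons = int(rng.integers(nlo, nhi + 1))
        exon_lens = rng.integers(elo, ehi + 1, size=n_exons)
        intron_lens = rng.integers(ilo, ihi + 1, size=max(0, n_exons - 1))
        structures.append((exon_lens, intron_lens))
        total += int(exon_lens.sum() + intron_lens.sum())
    slack = config.genome_length - total
    min_gap = 20
    if slack < (config.n_genes + 1) * min_gap:
        raise SimulationError(
            f"cannot place {config.n_genes} genes (need {total} bases plus gaps) "
            f"in a {config.genome_length} base genome"
        )
    weights = rng.random(config.n_genes + 1)
    gaps = min_gap + np.floor(weights / weights.sum() * (slack - (config.n_genes + 1) * min_gap)).astype(int)

    cursor = 1
    for gi, (exon_lens, intron_lens) in enumerate(structures):
        cursor += int(gaps[gi])
        exons = []
        pos = cursor
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos += int(el)
            if k < len(intron_lens):
                pos += int(intron_lens[k])
        genes.append(GeneModel(f"gene_{gi + 1:04d}", config.chrom, "+", exons))
        cursor = pos
    return genome, genes


# ---------------------------------------------------------------------------
# circRNA sampling
# ---------------------------------------------------------------------------

def _subtype_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n circles over the subtype mix."""
    raw = {s: mix.get(s, 0.0) * n for s in SUBTYPES}
    counts = {s: int(v) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s in sorted(SUBTYPES, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    return counts


def _draw_circle(subtype: str, genes: list[GeneModel], config: SimConfig,
                 rng: np.random.Generator) -> list[tuple[int, int]] | None:
    gene = genes[int(rng.integers(0, len(genes)))]
    exons = gene.exons
    n = len(exons)
    if subtype == "single_exon":
        cand = [e for e in exons if e[1] - e[0] + 1 >= config.read_len]
        if not cand:
            return None
        return [cand[int(rng.integers(0, len(cand)))]]
    if subtype == "small":
        cand = [e for e in exons if e[1] - e[0] + 1 < config.read_len]
        if not cand:
            return None
        return [cand[int(rng.integers(0, len(cand)))]]
    if n < 2:
        return None
    i = int(rng.integers(0, n - 1))
    j = int(rng.integers(i + 1, n))
    run = exons[i:j + 1]
    if subtype == "multi_exon":
        return list(run)
    if subtype == "intron_retained":
        # retain one intron: merge two adjacent exons across it
        k = int(rng.integers(0, len(run) - 1))
        merged = run[:k] + [(run[k][0], run[k + 1][1])] + run[k + 2:]
        return merged
    if subtype == "short_flank":
        terminal = run[0] if rng.random() < 0.5 else run[-1]
        if terminal[1] - terminal[0] + 1 >= config.read_len:
            return None
        return list(run)
    raise AssertionError(subtype)


def sample_circRNAs(genes: list[GeneModel], config: SimConfig,
                    rng: np.random.Generator | None = None,
                    max_retries: int = 500) -> list[TruthRecord]:
    """Draw ``n_circ`` circles according to the subtype mix.

    Junction boundaries land on exon edges of the source gene models (or on
    retained-intron edges); junctions are unique across the truth set.
    Raises :class:`SimulationError` if a subtype cannot be realised within
    the retry budget.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_circ == 0:
        return []
    if not genes:
        raise SimulationError("cannot sample circRNAs without gene models")
    counts = _subtype_counts(config.subtype_mix, config.n_circ)
    truth: list[TruthRecord] = []
    used: set[tuple[int, int]] = set()
    idx = 1
    for subtype in SUBTYPES:
        for _ in range(counts[subtype]):
            blocks = None
            for _attempt in range(max_retries):
                blocks = _draw_circle(subtype, genes, config, rng)
                if blocks is not None and (blocks[0][0], blocks[-1][1]) not in used:
                    break
                blocks = None
            if blocks is None:
                raise SimulationError(
                    f"could not realise subtype {subtype!r} within {max_retries} tries "
                    f"(exon length range {config.exon_length_range}, read_len {config.read_len})"
                )
            used.add((blocks[0][0], blocks[-1][1]))
            junction = Junction(config.chrom, blocks[0][0], blocks[-1][1])
            length = sum(e - s + 1 for s, e in blocks)
            truth.append(TruthRecord(f"circ_{idx:04d}", junction, subtype, blocks, length))
            idx += 1
    return truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _transcript_seq(genome: str, transcript: Transcript) -> str:
    return "".join(genome[s - 1:e] for s, e in transcript.blocks)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = choices[int(rng.integers(0, choices.shape[0]))]
    return arr.tobytes().decode("ascii")


def _fragment_reads(transcript: Transcript, tseq: str, n_pairs: int, prefix: str,
                    config: SimConfig, rng: np.random.Generator) -> list[tuple[SimulatedRead, SimulatedRead]]:
    R = config.read_len
    L = transcript.length
    pairs = []
    for p in range(n_pairs):
        flen = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        flen = max(flen, R)
        if transcript.circular:
            fstart = int(rng.integers(0, L))
        else:
            flen = min(flen, L)
            fstart = int(rng.integers(0, L - flen + 1))
        name = f"{prefix}_p{p + 1:05d}"

        def stored(tpos: int) -> str:
            if transcript.circular:
                idx = [(tpos + k) % L for k in range(R)]
                raw = "".join(tseq[i] for i in idx)
            else:
                raw = tseq[tpos:tpos + R]
            return _apply_errors(raw, rng, config.error_rate)

        r1 = SimulatedRead(name, 1, "+", stored(fstart), fstart, transcript)
        r2_start = (fstart + flen - R) % L if transcript.circular else fstart + flen - R
        r2 = SimulatedRead(name, 2, "-", stored(r2_start), r2_start, transcript)
        pairs.append((r1, r2))
    return pairs


def simulate_reads(truth: list[TruthRecord], genes: list[GeneModel], genome: str,
                   config: SimConfig, rng: np.random.Generator | None = None
                   ) -> list[tuple[SimulatedRead, SimulatedRead]]:
    """Sample FR paired-end reads from every linear and circular transcript.

    Pair count per transcript is ``round(depth * length / (2 * read_len))``;
    fragment starts are uniform on the (circularised) transcript, so BSJ and
    wrap-around reads arise naturally from the modular coordinates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    R = config.read_len
    all_pairs: list[tuple[SimulatedRead, SimulatedRead]] = []

    linear = [
        Transcript(g.gene_id, g.chrom, list(g.exons), circular=False)
        for g in genes
        if sum(e - s + 1 for s, e in g.exons) >= R
    ]
    if linear and config.insert_mean < R:
        raise SimulationError("insert_mean below read_len is not allowed for linear transcripts")
    for tr in linear:
        n_pairs = int(round(config.depth_linear * tr.length / (2 * R)))
        tseq = _transcript_seq(genome, tr)
        all_pairs.extend(_fragment_reads(tr, tseq, n_pairs, tr.name, config, rng))

    for rec in truth:
        tr = Transcript(rec.circ_id, rec.junction.chrom, rec.blocks, circular=True)
        n_pairs = int(round(config.depth_circ * tr.length / (2 * R)))
        tseq = _transcript_seq(genome, tr)
        pairs = _fragment_reads(tr, tseq, n_pairs, rec.circ_id, config, rng)
        rec.read_ids = [r1.name for r1, _ in pairs]
        all_pairs.extend(pairs)
    return all_pairs


# ---------------------------------------------------------------------------
# alignment emission
# ---------------------------------------------------------------------------

def genomic_segments(transcript: Transcript, tstart: int, length: int) -> list[tuple[int, int, int]]:
    """Decompose a transcript interval into genomic segments.

    Returns ``(genome_start, segment_length, read_offset)`` triples in read
    (stored-sequence) order, splitting wherever consecutive transcript bases
    are not adjacent on the genome (introns, back-spliced wrap).
    Coordinates are 1-based.
    """
    # genome position of each transcript base, block by block
    L = transcript.length
    positions = []
    t = tstart % L if transcript.circular else tstart
    remaining = length
    # precompute block offsets
    block_offsets = []
    off = 0
    for s, e in transcript.blocks:
        block_offsets.append((off, s, e - s + 1))
        off += e - s + 1
    while remaining > 0:
        for boff, bstart, blen in block_offsets:
            if boff <= t < boff + blen:
                take = min(blen - (t - boff), remaining)
                positions.append((bstart + (t - boff), take))
                t += take
                remaining -= take
                if transcript.circular and t >= L:
                    t = 0
                break
        else:
            raise AssertionError("transcript coordinate out of range")
        if not transcript.circular and t >= L and remaining > 0:
            raise SimulationError("read extends past a linear transcript")
    # merge genomically adjacent runs, track read offsets
    segments: list[tuple[int, int, int]] = []
    roff = 0
    for gstart, glen in positions:
        if segments and segments[-1][0] + segments[-1][1] == gstart:
            prev = segments[-1]
            segments[-1] = (prev[0], prev[1] + glen, prev[2])
        else:
            segments.append((gstart, glen, roff))
        roff += glen
    return segments


def emit_alignments(pairs: list[tuple[SimulatedRead, SimulatedRead]], config: SimConfig,
                    out_sam: str, supplementary_min: int = SUPPLEMENTARY_MIN) -> None:
    """Write the split alignments the simulated reads would receive.

    Single-segment reads get one full-match record.  Multi-segment reads are
    anchored on the longest genomic segment (clipping the rest); every other
    segment of at least ``supplementary_min`` bases whose span is not
    contained in the anchor's span yields a supplementary soft-clipped
    record.  A read wrapping a circle shorter than itself thus collapses to
    the double-clipped ``xSyMzS`` pattern on the full circle.  All records
    carry MAPQ 60 and correct mate placement, coordinate sorted.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": config.chrom, "LN": config.genome_length}]}
    )
    records = []

    def build(read: SimulatedRead, mate: SimulatedRead) -> None:
        segs = genomic_segments(read.transcript, read.tstart, config.read_len)
        # dedupe wrap-around revisits of the same genomic run (keep longest)
        anchor = max(range(len(segs)), key=lambda k: (segs[k][1], -k))
        a_start, a_len, a_off = segs[anchor]
        mate_segs = genomic_segments(mate.transcript, mate.tstart, config.read_len)
        m_anchor = max(range(len(mate_segs)), key=lambda k: (mate_segs[k][1], -k))
        mate_pos = mate_segs[m_anchor][0]

        def make(gstart: int, glen: int, roff: int, supplementary: bool) -> None:
            rec = pysam.AlignedSegment(header)
            rec.query_name = read.name
            rec.reference_id = 0
            rec.reference_start = gstart - 1
            rec.mapping_quality = 60
            cigar = []
            if roff:
                cigar.append((4, roff))
            cigar.append((0, glen))
            tail = config.read_len - roff - glen
            if tail:
                cigar.append((4, tail))
            rec.cigartuples = cigar
            flag = 0x1
            flag |= 0x40 if read.mate_index == 1 else 0x80
            if read.strand == "-":
                flag |= 0x10
            if mate.strand == "-":
                flag |= 0x20
            if supplementary:
                flag |= 0x800
            rec.flag = flag
            rec.query_sequence = read.seq_stored
            rec.query_qualities = pysam.qualitystring_to_array("I" * config.read_len)
            rec.next_reference_id = 0
            rec.next_reference_start = mate_pos - 1
            records.append(rec)

        make(a_start, a_len, a_off, supplementary=False)
        a_end = a_start + a_len - 1
        emitted_spans = [(a_start, a_end)]
        for k, (gstart, glen, roff) in enumerate(segs):
            if k == anchor or glen < supplementary_min:
                continue
            gend = gstart + glen - 1
            if any(gstart >= s and gend <= e for s, e in emitted_spans):
                continue  # wrap revisit of an already-reported span
            make(gstart, glen, roff, supplementary=True)
            emitted_spans.append((gstart, gend))

    for r1, r2 in pairs:
        build(r1, r2)
        build(r2, r1)

    records.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    with pysam.AlignmentFile(out_sam, "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


# ---------------------------------------------------------------------------
# file outputs and orchestration
# ---------------------------------------------------------------------------

def write_fasta(genome: str, config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{config.chrom}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i:i + 70] + "\n")


def write_gtf(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for k, (s, e) in enumerate(g.exons, 1):
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; exon_number "{k}";'
                fh.write(f"{g.chrom}\tcircjunction_sim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def write_fastq(pairs: list[tuple[SimulatedRead, SimulatedRead]], path1: str, path2: str) -> None:
    """Paired FASTQ in sequencing orientation (mate 2 is reverse-complemented)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            q = "I" * len(r1.seq_stored)
            f1.write(f"@{r1.name}/1\n{r1.seq_stored}\n+\n{q}\n")
            f2.write(f"@{r2.name}/2\n{reverse_complement(r2.seq_stored)}\n+\n{q}\n")


def write_truth(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tchrom\tstart\tend\tsubtype\tlength\n")
        for t in truth:
            j = t.junction
            fh.write(f"{t.circ_id}\t{j.chrom}\t{j.acceptor}\t{j.donor}\t{t.subtype}\t{t.circ_length}\n")


@dataclass
class SimResult:
    config: SimConfig
    genome: str
    genes: list[GeneModel]
    truth: list[TruthRecord]
    pairs: list[tuple[SimulatedRead, SimulatedRead]]
    sam_path: str | None = None


def run_simulation(config: SimConfig, outdir: str | None = None) -> SimResult:
    """Full simulation pass; writes FASTA/GTF/FASTQ/SAM/truth when ``outdir`` given."""
    rng = np.random.default_rng(config.seed)
    genome, genes = generate_genome(config, rng)
    truth = sample_circRNAs(genes, config, rng) if config.n_circ else []
    pairs = simulate_reads(truth, genes, genome, config, rng)
    result = SimResult(config, genome, genes, truth, pairs)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(genome, config, os.path.join(outdir, "genome.fa"))
        write_gtf(genes, os.path.join(outdir, "genes.gtf"))
        write_fastq(pairs, os.path.join(outdir, "reads_1.fastq"), os.path.join(outdir, "reads_2.fastq"))
        write_truth(truth, os.path.join(outdir, "truth.tsv"))
        sam_path = os.path.join(outdir, "alignments.sam")
        emit_alignments(pairs, config, sam_path)
        result.sam_path = sam_path
    return result
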