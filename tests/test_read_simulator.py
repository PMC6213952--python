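"""Synthetic genome, transcript and read generation, and alignment emission."""

import numpy as np
import pysam
import pytest
from Bio import SeqIO

from circjunction import SimConfig, SimulationError, generate_genome, run_simulation
from circjunction.read_simulator import (
    SimulatedRead,
    Transcript,
    _subtype_counts,
    _transcript_seq,
    emit_alignments,
    genomic_segments,
    sample_circRNAs,
    simulate_reads,
)


def _cfg(**kw):
    base = dict(genome_length=80_000, n_genes=8, n_circ=4, depth_circ=10,
                depth_linear=5, error_rate=0.0, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateGenome:
    def test_deterministic_under_seed(self, tmp_path):
        r1 = run_simulation(_cfg(), str(tmp_path / "a"))
        r2 = run_simulation(_cfg(), str(tmp_path / "b"))
        assert (tmp_path / "a" / "genome.fa").read_bytes() == (tmp_path / "b" / "genome.fa").read_bytes()
        assert (tmp_path / "a" / "reads_1.fastq").read_bytes() == (tmp_path / "b" / "reads_1.fastq").read_bytes()
        assert (tmp_path / "a" / "alignments.sam").read_bytes() == (tmp_path / "b" / "alignments.sam").read_bytes()
        assert r1.genome == r2.genome

    def test_exon_lengths_within_range_and_genes_disjoint(self):
        config = _cfg(exon_length_range=(100, 500), genome_length=200_000)
        _, genes = generate_genome(config)
        lo, hi = config.exon_length_range
        prev_end = 0
        for g in genes:
            for s, e in g.exons:
                assert lo <= e - s + 1 <= hi
            assert g.span[0] > prev_end
            prev_end = g.span[1]
            assert prev_end <= config.genome_length

    def test_zero_genes_gives_empty_annotation(self):
        genome, genes = generate_genome(_cfg(n_genes=0, n_circ=0))
        assert len(genome) == 80_000 and genes == []

    def test_overfull_genome_rejected(self):
        with pytest.raises(SimulationError, match="place"):
            generate_genome(_cfg(genome_length=5_000, n_genes=20))


class TestSampleCircRNAs:
    def test_all_small_subtype_shorter_than_read(self):
        config = _cfg(subtype_mix={"small": 1.0}, n_circ=6, read_len=100)
        _, genes = generate_genome(config)
        truth = sample_circRNAs(genes, config)
        assert len(truth) == 6
        assert all(t.circ_length < 100 for t in truth)

    def test_exact_subtype_proportions(self):
        counts = _subtype_counts({"multi_exon": 0.5, "intron_retained": 0.5}, 10)
        assert counts["multi_exon"] == 5 and counts["intron_retained"] == 5

    def test_junctions_on_exon_boundaries(self):
        config = _cfg(n_circ=12)
        _, genes = generate_genome(config)
        starts = {s for g in genes for s, _ in g.exons}
        ends = {e for g in genes for _, e in g.exons}
        for t in sample_circRNAs(genes, config):
            assert t.junction.acceptor in starts
            assert t.junction.donor in ends

    def test_intron_retained_longer_than_exons_alone(self):
        config = _cfg(subtype_mix={"intron_retained": 1.0}, n_circ=5)
        _, genes = generate_genome(config)
        for t in sample_circRNAs(genes, config):
            assert len(t.blocks) >= 1
            genomic = t.junction.donor - t.junction.acceptor + 1
            assert t.circ_length == sum(e - s + 1 for s, e in t.blocks)
            # a retained intron makes some block span an exon boundary gap
            assert any(
                (s, e) not in {ex for g in genes for ex in g.exons}
                for s, e in t.blocks
            )

    def test_impossible_subtype_raises(self):
        config = _cfg(subtype_mix={"small": 1.0}, read_len=20)
        _, genes = generate_genome(config)  # min exon length 30 > read_len
        with pytest.raises(SimulationError, match="small"):
            sample_circRNAs(genes, config)


class TestSimulateReads:
    def test_pair_count_follows_coverage_identity(self):
        genome = "ACGT" * 250
        tr = Transcript("t", "chrS", [(1, 1000)], circular=False)
        config = _cfg(genome_length=1000, n_genes=0, n_circ=0, depth_linear=10)
        rng = np.random.default_rng(0)
        from circjunction.read_simulator import _fragment_reads
        pairs = _fragment_reads(tr, genome, round(10 * 1000 / 200), "t", config, rng)
        assert len(pairs) == 50

    def test_error_free_reads_are_transcript_substrings(self, small_sim):
        genome = small_sim.genome
        for r1, r2 in small_sim.pairs[:300]:
            for read in (r1, r2):
                tseq = _transcript_seq(genome, read.transcript)
                if read.transcript.circular:
                    tseq = tseq * (len(read.seq_stored) // len(tseq) + 2)
                assert read.seq_stored in tseq

    def test_mean_linear_coverage_near_depth(self, small_sim):
        config = small_sim.config
        by_gene = {}
        for r1, r2 in small_sim.pairs:
            name = r1.transcript.name
            if not r1.transcript.circular:
                by_gene.setdefault(name, 0)
                by_gene[name] += 2 * config.read_len
        for g in small_sim.genes:
            length = sum(e - s + 1 for s, e in g.exons)
            if length >= 10 * config.read_len:
                cov = by_gene[g.gene_id] / length
                assert abs(cov - config.depth_linear) / config.depth_linear < 0.1

    def test_insert_below_read_length_rejected_for_linear(self):
        config = _cfg(insert_mean=50.0)
        genome, genes = generate_genome(config)
        with pytest.raises(SimulationError, match="insert"):
            simulate_reads([], genes, genome, config)


class TestGenomicSegments:
    def test_contiguous_read_single_segment(self):
        tr = Transcript("t", "c", [(101, 400)], circular=False)
        assert genomic_segments(tr, 10, 50) == [(111, 50, 0)]

    def test_split_at_intron(self):
        tr = Transcript("t", "c", [(101, 200), (301, 400)], circular=False)
        assert genomic_segments(tr, 80, 50) == [(181, 20, 0), (301, 30, 20)]

    def test_wrap_on_circle(self):
        tr = Transcript("t", "c", [(1001, 1080)], circular=True)  # 80 bp circle
        segs = genomic_segments(tr, 60, 100)
        assert segs[0] == (1061, 20, 0)
        assert segs[1] == (1001, 80, 20)


class TestEmitAlignments:
    def _reads_to_sam(self, tmp_path, reads, config):
        path = str(tmp_path / "out.sam")
        emit_alignments(reads, config, path)
        with pysam.AlignmentFile(path) as fh:
            return list(fh)

    def test_balanced_bsj_read_gets_primary_and_supplementary(self, tmp_path):
        config = _cfg(genome_length=10_000, n_genes=0, n_circ=0)
        tr = Transcript("c1", "chrS", [(1001, 2000)], circular=True)
        seq = "A" * config.read_len
        r1 = SimulatedRead("q", 1, "+", seq, 1000 - 70, tr)  # 70 donor-side + 30 acceptor-side
        r2 = SimulatedRead("q", 2, "-", seq, 300, tr)
        recs = self._reads_to_sam(tmp_path, [(r1, r2)], config)
        by_name = [r for r in recs if r.query_name == "q" and not r.is_read2]
        cigars = sorted(r.cigarstring for r in by_name)
        assert cigars == ["70M30S", "70S30M"]  # donor-side primary, acceptor-side supplementary
        assert any(r.is_supplementary for r in by_name)
        assert all(r.mapping_quality == 60 for r in recs)

    def test_unbalanced_split_drops_short_supplementary(self, tmp_path):
        config = _cfg(genome_length=10_000, n_genes=0, n_circ=0)
        tr = Transcript("c1", "chrS", [(1001, 2000)], circular=True)
        seq = "A" * config.read_len
        r1 = SimulatedRead("q", 1, "+", seq, 1000 - 95, tr)  # 95 / 5 split
        r2 = SimulatedRead("q", 2, "-", seq, 300, tr)
        recs = [r for r in self._reads_to_sam(tmp_path, [(r1, r2)], config)
                if not r.is_read2]
        assert len(recs) == 1
        assert recs[0].cigarstring == "95M5S"

    def test_small_circle_three_segment_pattern(self, tmp_path):
        config = _cfg(genome_length=10_000, n_genes=0, n_circ=0)
        tr = Transcript("c1", "chrS", [(1001, 1080)], circular=True)  # 80 bp circle
        seq = "A" * config.read_len
        r1 = SimulatedRead("q", 1, "+", seq, 70, tr)  # wraps the circle fully
        r2 = SimulatedRead("q", 2, "-", seq, 10, tr)
        recs = [r for r in self._reads_to_sam(tmp_path, [(r1, r2)], config)
                if not r.is_read2]
        assert len(recs) == 1
        assert recs[0].cigarstring == "10S80M10S"
        assert recs[0].reference_start + 1 == 1001

    def test_mate_fields_point_at_primary(self, tmp_path):
        config = _cfg(genome_length=10_000, n_genes=0, n_circ=0)
        tr = Transcript("c1", "chrS", [(1001, 2000)], circular=True)
        seq = "C" * config.read_len
        r1 = SimulatedRead("q", 1, "+", seq, 0, tr)
        r2 = SimulatedRead("q", 2, "-", seq, 500, tr)
        recs = self._reads_to_sam(tmp_path, [(r1, r2)], config)
        first = next(r for r in recs if not r.is_read2)
        assert first.next_reference_start + 1 == 1501
        assert first.mate_is_reverse


class TestRoundTrips:
    def test_outputs_parse_with_standard_readers(self, small_sim):
        fasta = list(SeqIO.parse(small_sim.sam_path.replace("alignments.sam", "genome.fa"), "fasta"))
        assert len(fasta) == 1
        assert len(fasta[0].seq) == small_sim.config.genome_length
        fq = list(SeqIO.parse(small_sim.sam_path.replace("alignments.sam", "reads_1.fastq"), "fastq"))
        assert len(fq) == len(small_sim.pairs)
        with pysam.AlignmentFile(small_sim.sam_path) as fh:
            n = sum(1 for _ in fh)
        assert n >= 2 * len(small_sim.pairs)
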