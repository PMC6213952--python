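# Methods

## Detection model

A back-spliced junction (BSJ) read consists of donor-side sequence followed
by acceptor-side sequence (in transcript order), so its alignment to the
linear reference is clipped: acceptor-anchored records have the donor-side
bases clipped at the 5′ end (reference orientation), donor-anchored records
have the acceptor-side bases clipped at the 3′ end. The detector treats
every alignment record of every read end independently — primary, secondary
and supplementary records all count (duplicates and QC-fail records are
skipped); hard-clipped records have their sequence reconstructed from the
same end's primary record and are dropped (with a logged count) when none
was seen. FLAG-0x4 records carry no coordinates and are ignored: "clipped"
always means partially aligned, not unaligned.

The decisive test is pairwise: two reads spanning the same junction must
share a subsequence containing bases on both sides of each read's clip
boundary. This rescues unbalanced BSJ reads, whose short segment was never
(or wrongly) mapped, because the *other* read of the pair supplies the
evidence that the clipped bases belong across the junction.

### Orientation of the PEM rule

For an unstranded FR library, the BSJ evidence of a circle appears on both
sequencing strands: forward reads anchored at the acceptor, reverse reads
anchored at the donor, and vice versa. The paired-end-mapping filter
therefore requires the mate on the same chromosome, inside the inferred
`[acceptor, donor]` interval (boundaries inclusive), and on the opposite
strand of the junction read, accepting both (+ read, − mate) and (− read,
+ mate) configurations. Pinning left-cluster reads to the forward strand
(the `strict_orientation` switch, with `library_layout` choosing which
strand is "forward") discards half of the usable support and makes
low-depth circles (≲ 3× coverage) essentially undetectable; the relaxed
rule is the default. Mates that are themselves clipped contribute their
leftmost mapped coordinate.

### Local alignment

Smith–Waterman with affine gaps, written as a numba-compiled dynamic
program: match +1, mismatch −1, gap open −2, gap extend −1 (standard
nucleotide local-alignment scores; a gap run of length k costs
`open + (k−1)·extend`, and N never matches). Determinism among co-optimal
alignments: the end cell with maximal score and smallest coordinates is
chosen and traceback prefers diagonal over vertical over horizontal moves.
"Gaps" are counted as gap *columns*, not runs. Acceptance thresholds
default to `ceil(0.02 × read length)` mismatches and as many gap columns
(2 for 100 bp reads, 1 for 50 bp), with a minimum similar-region length of
15 columns — long enough that a chance match between unrelated 100-mers is
improbable — and the region must span both reads' clip boundaries.

### Seeded pair evaluation

`accept_pair` is an exact, pure function, but the pipeline only runs the
dynamic program on read pairs that share an exact 12-mer. On a dense
synthetic genome (50 genes in 500 kb with a 200 kb span ceiling) the
constraint-passing cross product reaches ~10⁷ pairs, almost all of them
sequence-unrelated; the seed index reduces this to the related pairs plus a
small random-collision tail. The requirement is lossless in the error-free
limit (an overlap of ≥ 15 identical columns contains an exact 15-mer) and,
at a 1% substitution rate, a genuine similar region of typical length
(tens of columns) lacks a shared 12-mer with negligible probability. Pairs
may be evaluated under any worker partitioning; the accepted set is
identical for any worker count because evaluation is pure and the merged
result is canonically sorted.

### Clustering and final filters

Junction loci are clustered by single linkage: two junctions join when both
|Δacceptor| and |Δdonor| are ≤ 5 bases (absorbing micro-homology shifts
without merging distinct circles). The representative junction is the modal
member junction (ties to the smallest coordinates), keeping reported
junctions on observed loci. A read counts toward the acceptor side when it
is the left member of a pair and toward the donor side when it is the right
member; the same read name is never counted twice on one side. Final
filters: ≥ 2 distinct reads per splice site and mean mapping quality ≥ 10.
No GT–AG splice-motif filter is applied: the method is annotation- and
motif-free by design. All references are treated equally. Coordinates are
1-based inclusive throughout; only the BED writer converts to 0-based
half-open.

## Simulator

The simulator emulates a transcriptome read simulator plus a split-read
aligner at desk scale, so the detector can be exercised end-to-end without
external tools.

* **Genome and genes.** I.i.d. uniform ACGT sequence (default 500 kb); 50
  non-overlapping genes on the forward strand with 3–8 exons of 30–350 bp
  and introns of 100–600 bp, separated by random intergenic gaps. All genes
  sit on the + strand: the detector's geometry is strand-symmetric (BSJ
  evidence appears on both read strands regardless of the source strand),
  so this loses no generality here.
* **Circles.** 30 circles per run drawn over five subtypes
  (multi-exon 0.40, single-exon 0.20, intron-retained 0.15, shorter than
  the read 0.10, short flanking exon 0.15); junctions land on exon (or
  retained-intron) edges and are unique.
* **Reads.** Per transcript, `round(depth × length / (2 × read length))`
  FR pairs; fragment lengths ~ Normal(300, 30) (the simulator this emulates
  does not document its fragment distribution; a normal is assumed);
  fragment starts uniform on the (circularised) transcript, so BSJ and
  wrap-around reads arise from the modular coordinates; substitution errors
  at 1% per base by default, no indel errors, flat base qualities. Mate 1
  is written forward, mate 2 reverse-complemented.
* **Alignments.** Each read's transcript interval is decomposed into
  genomic segments (split at introns and at the back-splice wrap). One
  segment: a full-match record. Several: the longest segment anchors the
  primary record (other bases soft-clipped); every other segment of ≥ 19
  bases — the default minimum seed length of the aligner family being
  emulated — whose span is not already contained in the anchor's span
  yields a supplementary record. Reads wrapping a circle shorter than
  themselves therefore collapse to the double-clipped `xSyMzS` record on
  the full circle. This reproduces the unbalanced-split pathology (splits
  < 19 bases silently dropped) that the pairwise similarity test is
  designed to survive. MAPQ is 60 everywhere: the i.i.d. genome has no
  repeats, so every placement is unique.

One RNG stream (PCG64, seeded by `SimConfig.seed`) is consumed in a fixed
order — genome, gene models, circles, reads, errors — making every output
byte-reproducible.

### What the simulator does not emulate

Real genomes carry repeats, segmental duplications and homologous gene
families; real aligners mis-place reads there, produce sub-60 MAPQ records
and fortuitous clips. Those processes are the main source of both missed
circles and false junctions on real data, and they are absent here. Passing
the simulated benchmarks therefore demonstrates the correctness of the
detection logic and its behaviour under depth, read-length and
linear-background variation — not real-data precision. Two consequences are
visible in the numbers: desk-scale sensitivity saturates at 1.0 for
circular depth ≥ 20× (real-data peak sensitivity is lower because of
mapping ambiguity), and the only false positives are splice artifacts —
a circle whose flanking exon is shorter than the read supports a spurious
sub-junction (next-exon start, true donor), and a short exon of a highly
covered linear gene can mimic a single-exon circle when both members'
mates land inside it. These artifacts are genuine properties of clip-based
detection, not simulator defects; they keep measured precision near 0.9 at
matched depths.

## Benchmark problem sizes

The benchmark harness (`circjunction.benchmark`, driven by
`scripts/acceptance.py` and the acceptance tests) uses a 500 kb genome,
50 genes and 30 circles per run, with three seeded replicates per
condition — the package's chosen desk scale, large enough that each
sensitivity estimate averages 90 truth junctions while a full sweep stays
within minutes on one CPU. Simulation scoring uses a boundary tolerance of
0 (the truth is exact); 5 bases is suggested when comparing callers on
real data.

## Known limitations

* No rescue of pairs whose mates are unmapped, and no realignment: the
  input aligner's records are taken as given.
* BSJ counts are the only quantification; internal circle structure is not
  reconstructed.
* The greedy closest-distance matching in evaluation can differ from an
  optimal assignment when truth junctions overlap within the tolerance;
  with exact simulation scoring (tolerance 0) the two coincide.
* The FDR of the RNase-R criterion applies the fold-change rule only; no
  additional cutoff is imposed on the treated-sample BSJ count.
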