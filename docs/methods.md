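# Methods

## Coordinates and orientation

All interval arithmetic is 0-based half-open on the + reference frame; GTF
I/O converts to and from the 1-based inclusive convention, SAM I/O follows
the SAM specification via pysam. Intron ordinals, splice-site windows,
intron sequences and motif scans are always in transcript (5′→3′)
orientation — on the − strand windows are taken from the opposite genomic
edges and reverse-complemented. U and T are interchangeable at every
sequence ingress (sequences are normalised to the DNA alphabet), because
annotation is DNA-framed while m6A motifs are usually written as RNA.

## Spanning-read selection and classification

A read informs the joint state of the two introns flanking a target exon
when (i) every exonic reference base is consumed by an aligned
match/mismatch block, where deletions of ≤ 3 nt (configurable) are absorbed
into blocks so that small indels do not discard informative reads, and (ii)
at least `min_overhang` (default 2) aligned bases lie beyond each exon
boundary — inside the adjacent intron for a contiguous alignment, or inside
the adjacent exon across an alignment gap. Default alignment filters:
primary alignments only, MAPQ ≥ 1, duplicates kept; paired-end mates are
treated as independent reads.

Per flanking intron the call is SPLICED when the read has a CIGAR-N gap
exactly matching the annotated intron interval *and* ≥ `min_overhang`
aligned bases immediately across the junction (mirroring the retained-side
rule); RETAINED when an aligned block runs contiguously ≥ `min_overhang` nt
past the exon boundary into the intron; anything else — a junction that
does not match the annotation, a junction into the intron interior, a long
deletion or clipped alignment at the boundary — makes the read AMBIGUOUS.
Ambiguous reads are counted and reported but excluded from all statistics,
since they carry no pattern information. The pair of per-intron calls maps
onto the four classes SS / RS / SR / RR.

The sashimi junction-coverage floor is `fraction × total_junction_reads /
n_introns` (default fraction 0.05), reported both as an exact rational and
rounded half-up to an integer read count for display.

## Dependence statistics

Retention efficiencies are the informative-read marginals with binomial
standard errors. The independence ("Punnett-square") expectation multiplies
the estimated marginals: `E_RR = n·p_up·p_down` and so on. The default test
is the Pearson goodness-of-fit of the four observed counts against this
expectation with df = 1 (4 cells − 1 − 2 estimated marginals); it is
algebraically the uncorrected 2×2 chi-square of independence, which the test
suite uses as an independent cross-check. A conditional exact (Fisher) test
is available as `method="exact"`, is reported alongside whenever any
expected cell is below 5, and replaces the Pearson statistic entirely when a
marginal is exactly 0 or 1 (degenerate expectation). The effect size is the
odds ratio `(RR·SS)/(RS·SR)`; the Haldane–Anscombe +0.5 correction is
applied to all four cells iff any cell is zero, and the SE of the log odds
ratio is the usual delta-method `sqrt(Σ 1/cell)`.

## Maximum-entropy splice-site models

The donor model scores a 9-mer (3 exonic + 6 intronic bases) as
`log2(consensus · table[rest])`: a consensus term for the near-invariant GT
at intron positions +1/+2 (consensus frequency over background frequency for
each base) times one joint table entry over the remaining 7 positions. The
acceptor model scores a 23-mer (20 intronic + 3 exonic); after removing the
invariant AG the maximum-entropy approximation over the remaining 21
positions is the product of five 7-mer component models divided by four
overlap models (windows 1–7, 8–14, 15–21, 5–11, 12–18 over the 21-mer, with
overlaps 5–7, 8–11, 12–14, 15–18), times the AG consensus term. Scores are
log₂-odds in bits.

Model tables are external inputs, never vendored: one value per line in
lexicographic A<C<G<T order (`me2x5`; `me2x3acc1`–`me2x3acc9`), each file
holding 4^k entries for its sub-model width, validated for size and
positivity at load. The published background (A/T 0.27, C/G 0.23) and
consensus-dinucleotide frequencies are built-in defaults; a
`consensus.json` in the model directory overrides them, which is how the
uniform test fixture (all table values 1, consensus = background = 0.25)
makes both scorers return exactly 0 bits on every input — a structural
identity the test suite asserts, together with hand-computed decompositions
of the consensus and table terms. Sites whose windows contain N are not
scored (reference scorers reject ambiguous bases) but remain in the
length/GC populations, with N excluded from the GC denominator.

## Population profiling

The genome-wide reference population consists of internal introns (neither
first nor last) of transcripts with ≥ 3 introns. By default one record is
kept per distinct (chrom, start, end, strand) locus so introns shared by
isoforms are not double-weighted; `per_transcript=True` keeps every copy,
and the output table records which mode produced it. Percentile ranks use
the mid-rank convention, `100·(#{p<x} + ½·#{p=x})/N`, which is symmetric
under ties and matches a brute-force ranking oracle in the tests.

Branch-point positions are consumed from a table (already in working
coordinates), never predicted. The reported distance is the number of
nucleotides strictly between the branch-point adenosine and the first base
of the intron's 3′-terminal dinucleotide, in transcript orientation; a
branch point outside its intron is a validation error. The "AG exclusion
zone" helper reports the distance from the branch point to the nearest
downstream AG — our operational definition, clearly separated from the
table-derived distance.

## Synthetic data

The generator emulates the one situation the classifier is built for: a
multi-exon gene, a short internal target exon, and two flanking introns
retained with marginal probabilities (`p_up`, `p_down`) and odds-ratio
dependence `theta` at the *molecule* level — each simulated RNA molecule has
a joint retention state, which is what "co-retained in the same transcript"
means; all non-target introns are always spliced, isolating the two-intron
question. For given margins and `theta ≠ 1` the RR cell probability is the
admissible root of the standard quadratic for a 2×2 table with fixed margins
and odds ratio; at `theta = 1` it is the product of the margins.

Default conditions: five exons of 150/120/40/120/150 nt with introns
400/350/350/400 nt (the 40-nt target exon mirrors the fact that a standard
100-nt short read must span the exon with overhangs to be informative, as
with the small FUS exon 7), `p_up = p_down = 0.3`, `theta = 4`, 20 000
reads of 100 nt, no sequencing errors. A read's originating molecule is
drawn with probability proportional to `p_class × (molecule length − read
length + 1)` — fragmentation produces reads in proportion to molecule
length — and its start is uniform along the molecule. This weighting is what
makes class sampling among exon-spanning reads unbiased: every molecule
contains the same number of spanning windows regardless of which introns it
retains, so with per-molecule-uniform sampling the longer (retained)
molecules would be under-represented and the estimated odds ratio biased
away from the generating value.

Alignment is emulated: reads are written at their true positions with true
CIGARs (M blocks, N gaps at spliced junctions); sequencing errors substitute
bases uniformly at `error_rate` without touching the gapped structure.
Outputs (GTF, FASTA, SAM, truth TSV, config echo) are byte-deterministic per
seed. Consequently passing tests demonstrate correctness of the
classification and inference machinery, not robustness to mapping errors,
coverage biases, PCR duplicates or mis-annotation, which the generator does
not model.

## Monte-Carlo problem sizes

Calibration studies sample informative-read pattern counts directly from the
joint distribution (a multinomial shortcut equivalent to the read-level
generator restricted to informative reads): 1000 replicates at `theta = 1`,
n = 2000, marginals 0.3 for the type-I error of the Pearson test at
α = 0.05, and 500 replicates at `theta = 9` for power. Odds-ratio recovery
runs the full read pipeline (simulate → select → classify → estimate) for
200 replicates of 20 000 reads at `theta = 4`, checking the median estimate
and the ±1.96·SE log-OR interval coverage. These sizes keep each study's
Monte-Carlo error well below the acceptance bands while the whole suite runs
in a couple of minutes.

## Known limitations

- The percentile profile of a real gene requires external inputs (GENCODE
  annotation, genome FASTA, published MaxEnt tables, a branch-point table);
  the repository tests exercise the identical code paths on synthetic
  populations and uniform model fixtures instead.
- The scorer consensus constants are built-in defaults of the published
  models; exotic model distributions can override them via
  `consensus.json`.
- Only one target exon flanked by two introns is modelled; joint models
  over > 2 introns and fragment-level (mate-merged) calling are out of
  scope, as are aligner emulation and transcript quantification.
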