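"""Synthetic gene, reference and spliced-read generator with controlled co-retention.

The generator emulates the situation the classifier is built for: a multi-exon
gene in which every transcript molecule retains each of the two introns
flanking a target exon with stated marginal probabilities, the joint
distribution of the two retention events having a stated odds ratio.  All
other introns are always spliced, isolating the two-intron dependence.
Reads are fixed-length windows drawn uniformly along each molecule and are
written as alignments at their true positions with true CIGARs (alignment is
emulated, not re-run); sequencing errors substitute bases but never change
the gapped structure.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from ._seq import revcomp
from .gene_model import TranscriptModel, derive_introns, write_gtf
from .read_classification import PatternClass, PatternCounts, SpanningRead

_CLASS_ORDER = ("RR", "RS", "SR", "SS")
_CLASS_ENUM = {
    "SS": PatternClass.BOTH_SPLICED,
    "RS": PatternClass.R_UP_S_DOWN,
    "SR": PatternClass.S_UP_R_DOWN,
    "RR": PatternClass.BOTH_RETAINED,
}


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic gene and its reads.

    Defaults describe a five-exon gene with a short target exon (so a
    standard 100-nt short read can span it with overhangs), moderate marginal
    retention of the two flanking introns, and positive co-retention.
    """

    exon_lengths: tuple[int, ...] = (150, 120, 40, 120, 150)
    intron_lengths: tuple[int, ...] = (400, 350, 350, 400)
    target_exon_ordinal: int = 3
    p_up: float = 0.3
    p_down: float = 0.3
    theta: float = 4.0
    n_reads: int = 20000
    read_length: int = 100
    error_rate: float = 0.0
    strand: str = "+"
    chrom: str = "chrSim"
    flank: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if not (1 < self.target_exon_ordinal < len(self.exon_lengths)):
            raise ValueError("target exon must be internal (flanked by two introns)")
        if not (0.0 <= self.p_up <= 1.0 and 0.0 <= self.p_down <= 1.0):
            raise ValueError("retention marginals must lie in [0, 1]")
        if self.theta <= 0:
            raise ValueError("odds ratio theta must be > 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0, 1)")
        if min(self.exon_lengths) < 2 or min(self.intron_lengths) < 2:
            raise ValueError("exon and intron lengths must be >= 2 nt")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length must be >= 1 and n_reads >= 0")


def joint_from_or(p_up: float, p_down: float, theta: float) -> dict[str, float]:
    """Joint cell probabilities (RR, RS, SR, SS) with given marginals and odds ratio.

    For theta != 1 the RR cell is the admissible root of the standard
    quadratic for a 2x2 table with fixed margins and odds ratio
    theta = (p_RR * p_SS) / (p_RS * p_SR); for theta = 1 it is the
    independence product.
    """
    if not (0.0 < p_up < 1.0 and 0.0 < p_down < 1.0):
        raise ValueError("marginals must lie strictly inside (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if theta == 1.0:
        p_rr = p_up * p_down
    else:
        a = 1.0 + (p_up + p_down) * (theta - 1.0)
        disc = a * a - 4.0 * theta * (theta - 1.0) * p_up * p_down
        if disc < 0:
            raise ValueError("no admissible root for the requested margins/theta")
        p_rr = (a - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    cells = {
        "RR": p_rr,
        "RS": p_up - p_rr,
        "SR": p_down - p_rr,
        "SS": 1.0 - p_up - p_down + p_rr,
    }
    if min(cells.values()) < -1e-12:
        raise ValueError("no admissible joint distribution (negative cell)")
    return {k: max(v, 0.0) for k, v in cells.items()}


@dataclass
class SyntheticGene:
    """In-memory result of simulate_gene: model + reference sequence."""

    config: SimConfig
    transcript: TranscriptModel
    sequence: str  # full chromosome, forward strand

    @property
    def genome(self) -> dict[str, str]:
        return {self.config.chrom: self.sequence}


def simulate_gene(config: SimConfig, out_prefix: str | None = None) -> SyntheticGene:
    """Build the annotated gene and its chromosome; optionally write GTF + FASTA.

    The chromosome is seeded random sequence with GT/AG dinucleotides planted
    at every intron boundary (transcript orientation); deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    gene_len = sum(config.exon_lengths) + sum(config.intron_lengths)
    chrom_len = gene_len + 2 * config.flank
    seq = rng.choice(list("ACGT"), size=chrom_len)

    # exon intervals left-to-right on the genome; transcript order follows strand
    lengths_lr = (
        list(config.exon_lengths)
        if config.strand == "+"
        else list(config.exon_lengths)[::-1]
    )
    introns_lr = (
        list(config.intron_lengths)
        if config.strand == "+"
        else list(config.intron_lengths)[::-1]
    )
    exons_lr: list[tuple[int, int]] = []
    pos = config.flank
    for i, elen in enumerate(lengths_lr):
        exons_lr.append((pos, pos + elen))
        pos += elen
        if i < len(introns_lr):
            pos += introns_lr[i]

    # plant splice dinucleotides in transcript orientation
    for (s0, e0), (s1, _) in zip(exons_lr, exons_lr[1:]):
        if config.strand == "+":
            seq[e0], seq[e0 + 1] = "G", "T"  # donor GT at intron start
            seq[s1 - 2], seq[s1 - 1] = "A", "G"  # acceptor AG at intron end
        else:
            seq[s1 - 2], seq[s1 - 1] = "A", "C"  # revcomp(GT) at transcript donor
            seq[e0], seq[e0 + 1] = "C", "T"  # revcomp(AG) at transcript acceptor

    exons_tx = tuple(exons_lr if config.strand == "+" else exons_lr[::-1])
    transcript = TranscriptModel(
        transcript_id="SIMT0001",
        chrom=config.chrom,
        strand=config.strand,
        exons=exons_tx,
    )
    gene = SyntheticGene(config=config, transcript=transcript, sequence="".join(seq))
    if out_prefix is not None:
        write_gtf([transcript], f"{out_prefix}.gtf")
        with open(f"{out_prefix}.fa", "w") as fh:
            fh.write(f">{config.chrom}\n")
            for i in range(0, chrom_len, 60):
                fh.write(gene.sequence[i : i + 60] + "\n")
    return gene


@dataclass
class SimulatedRead:
    """One emitted read: genomic block structure plus its provenance."""

    read_id: str
    molecule_id: str
    truth_class: str  # RR / RS / SR / SS
    informative: bool
    blocks: tuple[tuple[int, int], ...]  # ascending genomic intervals
    junction_gaps: tuple[tuple[int, int], ...]
    sequence: str  # forward-genome orientation

    def to_spanning_read(self, chrom: str, strand: str) -> SpanningRead:
        gaps = tuple((iv, "N") for iv in self.junction_gaps)
        return SpanningRead(
            read_id=self.read_id,
            chrom=chrom,
            strand=strand,
            blocks=self.blocks,
            gaps=gaps,
        )


@dataclass
class TruthTable:
    """Per-molecule labels, per-read provenance and realized joint counts."""

    reads: list[SimulatedRead]
    realized_counts: dict[str, int]

    def informative_counts(self) -> PatternCounts:
        c = {k: 0 for k in _CLASS_ORDER}
        for r in self.reads:
            if r.informative:
                c[r.truth_class] += 1
        return PatternCounts(
            n_SS=c["SS"], n_RS=c["RS"], n_SR=c["SR"], n_RR=c["RR"], n_ambiguous=0
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [r.read_id for r in self.reads],
                "molecule_id": [r.molecule_id for r in self.reads],
                "truth_class": [r.truth_class for r in self.reads],
                "informative": [r.informative for r in self.reads],
                "start": [r.blocks[0][0] for r in self.reads],
            }
        )


def _molecule_segments(gene: SyntheticGene, truth_class: str) -> list[tuple[int, int]]:
    """Genomic segments of one molecule in transcript order.

    All exons, plus the upstream/downstream flanking intron when retained;
    non-target introns are always spliced.
    """
    t = gene.transcript
    cfg = gene.config
    introns = derive_introns(t)
    up_idx = cfg.target_exon_ordinal - 1  # intron ordinal upstream of target exon
    down_idx = cfg.target_exon_ordinal
    retained = set()
    if truth_class in ("RR", "RS"):
        retained.add(up_idx)
    if truth_class in ("RR", "SR"):
        retained.add(down_idx)
    segments: list[tuple[int, int]] = []
    for i, exon in enumerate(t.exons, start=1):
        segments.append(exon)
        if i <= len(introns) and i in retained:
            segments.append(introns[i - 1].interval)
    # merge transcript-adjacent segments that are also genomically contiguous
    merged: list[tuple[int, int]] = []
    for s, e in segments:
        if merged:
            ps, pe = merged[-1]
            if (cfg.strand == "+" and pe == s) or (cfg.strand == "-" and ps == e):
                merged[-1] = (min(ps, s), max(pe, e))
                continue
        merged.append((s, e))
    return merged


def _target_exon_span(gene: SyntheticGene, segments: list[tuple[int, int]]) -> tuple[int, int]:
    """Molecule-coordinate [start, end) of the target exon."""
    exon = gene.transcript.exons[gene.config.target_exon_ordinal - 1]
    offset = 0
    for s, e in segments:
        lo = offset
        hi = offset + (e - s)
        if (s, e) == exon or (s <= exon[0] and exon[1] <= e):
            if gene.config.strand == "+":
                return lo + (exon[0] - s), lo + (exon[1] - s)
            return lo + (e - exon[1]), lo + (e - exon[0])
        offset = hi
    raise AssertionError("target exon not found in molecule segments")


def _window_to_blocks(
    segments: list[tuple[int, int]], strand: str, t0: int, length: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Map a molecule-coordinate window to ascending genomic blocks + junction gaps."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in segments:
        seg_len = e - s
        lo = max(t0, offset)
        hi = min(t0 + length, offset + seg_len)
        if hi > lo:
            if strand == "+":
                blocks.append((s + (lo - offset), s + (hi - offset)))
            else:
                blocks.append((e - (hi - offset), e - (lo - offset)))
        offset += seg_len
    blocks.sort()
    gaps = [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
    return blocks, gaps


def simulate_reads(gene: SyntheticGene, out_prefix: str | None = None) -> TruthTable:
    """Draw molecules from the joint retention distribution and emit reads.

    One read per molecule, its start uniform along the molecule.  Optionally
    writes a SAM file, a truth TSV and a config echo JSON under
    ``out_prefix``.
    """
    cfg = gene.config
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the gene builder
    if 0 < cfg.p_up < 1 and 0 < cfg.p_down < 1:
        joint = joint_from_or(cfg.p_up, cfg.p_down, cfg.theta)
    else:
        joint = _degenerate_joint(cfg)  # a margin is 0 or 1; theta is irrelevant

    seg_cache = {k: _molecule_segments(gene, k) for k in _CLASS_ORDER}
    span_cache = {k: _target_exon_span(gene, seg_cache[k]) for k in _CLASS_ORDER}
    len_cache = {k: sum(e - s for s, e in seg_cache[k]) for k in _CLASS_ORDER}
    for k, mol_len in len_cache.items():
        if cfg.read_length > mol_len:
            raise ValueError(
                f"read_length {cfg.read_length} exceeds molecule length {mol_len} "
                f"for class {k}"
            )
    # fragmentation yields reads in proportion to molecule length, so a read's
    # originating molecule is drawn with probability proportional to
    # p_class * (windows per molecule); every molecule then contributes the
    # same number of exon-spanning windows, keeping class sampling unbiased
    weights = np.array(
        [joint[k] * (len_cache[k] - cfg.read_length + 1) for k in _CLASS_ORDER]
    )
    probs = weights / weights.sum()
    class_idx = rng.choice(len(_CLASS_ORDER), size=cfg.n_reads, p=probs)

    offsets = rng.random(cfg.n_reads)
    reads: list[SimulatedRead] = []
    realized = {k: 0 for k in _CLASS_ORDER}
    min_ov = 2
    for i in range(cfg.n_reads):
        klass = _CLASS_ORDER[class_idx[i]]
        realized[klass] += 1
        segments = seg_cache[klass]
        mol_len = len_cache[klass]
        t0 = int(offsets[i] * (mol_len - cfg.read_length + 1))
        blocks, gaps = _window_to_blocks(segments, cfg.strand, t0, cfg.read_length)
        exon_lo, exon_hi = span_cache[klass]
        informative = t0 + min_ov <= exon_lo and t0 + cfg.read_length - min_ov >= exon_hi
        seq = "".join(gene.sequence[s:e] for s, e in blocks)
        reads.append(
            SimulatedRead(
                read_id=f"read{i:06d}",
                molecule_id=f"mol{i:06d}",
                truth_class=klass,
                informative=informative,
                blocks=tuple(blocks),
                junction_gaps=tuple(gaps),
                sequence=seq,
            )
        )

    if cfg.error_rate > 0:
        _apply_errors(reads, cfg.error_rate, rng)

    truth = TruthTable(reads=reads, realized_counts=realized)
    if out_prefix is not None:
        _write_sam(gene, reads, f"{out_prefix}.sam")
        truth.to_frame().to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
        with open(f"{out_prefix}.config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=2, default=list)
            fh.write("\n")
    return truth


def _degenerate_joint(cfg: SimConfig) -> dict[str, float]:
    """Joint distribution when a marginal is exactly 0 or 1 (theta irrelevant)."""
    pu, pd_ = cfg.p_up, cfg.p_down
    return {
        "RR": pu * pd_,
        "RS": pu * (1 - pd_),
        "SR": (1 - pu) * pd_,
        "SS": (1 - pu) * (1 - pd_),
    }


_BASES = np.array(list("ACGT"))


def _apply_errors(reads: list[SimulatedRead], rate: float, rng: np.random.Generator) -> None:
    """Uniform base substitutions at ``rate``; gapped structure untouched."""
    for r in reads:
        seq = np.array(list(r.sequence))
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        for pos in hits:
            choices = _BASES[_BASES != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        r.sequence = "".join(seq)


def _cigar(read: SimulatedRead) -> list[tuple[int, int]]:
    cig: list[tuple[int, int]] = []
    for j, (s, e) in enumerate(read.blocks):
        cig.append((0, e - s))  # M
        if j < len(read.junction_gaps):
            g0, g1 = read.junction_gaps[j]
            cig.append((3, g1 - g0))  # N
    return cig


def _write_sam(gene: SyntheticGene, reads: list[SimulatedRead], path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": gene.config.chrom, "LN": len(gene.sequence)}],
        "PG": [{"ID": "retentia-sim", "PN": "retentia"}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 60
            a.cigartuples = _cigar(r)
            a.query_sequence = r.sequence
            a.flag = 16 if gene.config.strand == "-" else 0
            a.set_tag("TC", r.truth_class)
            out.write(a)


def sort_and_index(sam_path: str) -> str:
    """Produce a coordinate-sorted, indexed BAM next to a SAM file."""
    bam_path = os.path.splitext(sam_path)[0] + ".sorted.bam"
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path


def simulate_pattern_counts(
    p_up: float, p_down: float, theta: float, n: int, rng: np.random.Generator
) -> PatternCounts:
    """Draw informative-read pattern counts directly from the joint distribution.

    Counts-level shortcut for Monte-Carlo studies of the dependence test
    (equivalent to the read-level generator restricted to informative reads).
    """
    joint = joint_from_or(p_up, p_down, theta)
    rr, rs, sr, ss = rng.multinomial(n, [joint[k] for k in _CLASS_ORDER])
    return PatternCounts(n_SS=int(ss), n_RS=int(rs), n_SR=int(sr), n_RR=int(rr))


def make_maxent_fixture(out_dir: str) -> str:
    """Write uniform model tables (reference file layout) under ``out_dir``.

    All table values are 1 and consensus frequencies equal the uniform
    background, so both scorers return exactly 0 bits on every input.
    """
    os.makedirs(out_dir, exist_ok=True)
    sizes = {"me2x5": 4**7}
    for i, width in enumerate([7, 7, 7, 7, 7, 3, 4, 3, 4], start=1):
        sizes[f"me2x3acc{i}"] = 4**width
    for name, n in sizes.items():
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write("1\n" * n)
    uniform = {b: 0.25 for b in "ACGT"}
    with open(os.path.join(out_dir, "consensus.json"), "w") as fh:
        json.dump(
            {
                "background": uniform,
                "donor_consensus": [uniform, uniform],
                "acceptor_consensus": [uniform, uniform],
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return out_dir
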