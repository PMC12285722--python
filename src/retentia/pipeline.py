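"""End-to-end conveniences tying the generator, classifier and statistics together."""

from __future__ import annotations

from .coretention_stats import report as stats_report
from .gene_model import derive_introns
from .read_classification import (
    PatternCounts,
    classify_read,
    select_spanning,
    tally,
)
from .synthetic_data import SimConfig, SyntheticGene, TruthTable, simulate_gene, simulate_reads


def classify_truth_table(
    gene: SyntheticGene, truth: TruthTable, min_overhang: int = 2
) -> tuple[PatternCounts, list]:
    """Run selection + classification over simulated reads; returns (counts, labels)."""
    cfg = gene.config
    introns = derive_introns(gene.transcript)
    intron_up = introns[cfg.target_exon_ordinal - 2]
    intron_down = introns[cfg.target_exon_ordinal - 1]
    exon = gene.transcript.exons[cfg.target_exon_ordinal - 1]
    reads = [r.to_spanning_read(cfg.chrom, cfg.strand) for r in truth.reads]
    selected = select_spanning(reads, exon, min_overhang=min_overhang)
    labels = [
        classify_read(r, intron_up, intron_down, min_overhang=min_overhang)
        for r in selected
    ]
    return tally(labels), labels


def run_synthetic_pipeline(config: SimConfig, method: str = "pearson") -> dict:
    """Simulate a gene + reads, classify, and report the dependence statistics."""
    gene = simulate_gene(config)
    truth = simulate_reads(gene)
    counts, _ = classify_truth_table(gene, truth)
    out = stats_report(counts, method=method)
    out["realized_molecule_counts"] = truth.realized_counts
    return out
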