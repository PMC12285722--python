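"""Maximum-entropy splice-site scoring and genome-wide intron feature profiling.

The donor (5'ss) model scores a 9-mer — 3 exonic + 6 intronic bases — as the
log2 odds of the site under a maximum-entropy sequence model versus a
background composition: a consensus-dinucleotide term for the near-invariant
GT at intron positions +1/+2 times a full joint table over the remaining
7 positions.

The acceptor (3'ss) model scores a 23-mer — 20 intronic + 3 exonic bases.
After removing the invariant AG (positions 19-20 of the window), the
maximum-entropy approximation over the remaining 21 positions is the product
of five 7-mer component models divided by four overlap models, again times
the AG consensus term.

Model tables are external inputs in the reference distribution's text layout:
one probability ratio per line, ordered lexicographically over {A,C,G,T}
(A=0..T=3, big-endian); ``me2x5`` for the donor, ``me2x3acc1``..``me2x3acc9``
for the acceptor.  Background and consensus-dinucleotide frequencies default
to the published model constants and may be overridden by a ``consensus.json``
file in the same directory (used by uniform test fixtures).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from ._seq import normalize, revcomp
from .gene_model import (
    IntronRecord,
    TranscriptModel,
    derive_introns,
    splice_site_sequences,
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Published model constants: background composition and the consensus
# dinucleotide frequencies (GT for donors, AG for acceptors).
DEFAULT_BACKGROUND = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
DONOR_CONSENSUS = (
    {"A": 0.0040, "C": 0.0032, "G": 0.9896, "T": 0.0028},  # intron position +1 (G)
    {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884},  # intron position +2 (T)
)
ACCEPTOR_CONSENSUS = (
    {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030},  # intron position -2 (A)
    {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030},  # intron position -1 (G)
)

# windows over the 21-mer (acceptor 23-mer with the AG removed): five
# component 7-mers, then the four overlap models they double-count
_ACCEPTOR_WINDOWS = [
    (0, 7),
    (7, 14),
    (14, 21),
    (4, 11),
    (11, 18),
    (4, 7),
    (7, 11),
    (11, 14),
    (14, 18),
]


class ModelLoadError(ValueError):
    """Raised when a model table file is missing, truncated, or non-positive."""


class ScoringError(ValueError):
    """Raised for sequences the scorer cannot handle (wrong length, N, ...)."""


def _seq_index(seq: str) -> int:
    idx = 0
    for base in seq:
        idx = idx * 4 + _BASE_INDEX[base]
    return idx


@dataclass(frozen=True)
class MaxEntModel:
    """One maximum-entropy splice-site model (donor5 or acceptor3)."""

    kind: str  # 'donor5' | 'acceptor3'
    tables: tuple[np.ndarray, ...]
    background: Mapping[str, float]
    consensus: tuple[Mapping[str, float], Mapping[str, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("donor5", "acceptor3"):
            raise ModelLoadError(f"unknown model kind {self.kind!r}")
        expected = (4**7,) if self.kind == "donor5" else tuple(
            4 ** (hi - lo) for lo, hi in _ACCEPTOR_WINDOWS
        )
        sizes = tuple(len(t) for t in self.tables)
        if sizes != expected:
            raise ModelLoadError(
                f"{self.kind}: table sizes {sizes} do not match expected {expected}"
            )
        for i, t in enumerate(self.tables):
            if not np.all(t > 0):
                raise ModelLoadError(f"{self.kind}: table {i} contains non-positive values")
        for freqs in (self.background, *self.consensus):
            if set(freqs) != set("ACGT") or min(freqs.values()) <= 0:
                raise ModelLoadError(f"{self.kind}: invalid frequency map {dict(freqs)}")


def _read_table(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise ModelLoadError(f"model table file missing: {path}")
    values = np.loadtxt(path, dtype=float, ndmin=1)
    n = len(values)
    k = round(math.log(n, 4)) if n else 0
    if n == 0 or 4**k != n:
        raise ModelLoadError(
            f"{path}: {n} lines; expected 4^k one-value-per-line entries in "
            f"lexicographic A<C<G<T order"
        )
    return values


def _read_consensus(dir_: str):
    path = os.path.join(dir_, "consensus.json")
    if not os.path.exists(path):
        return None
    with open(path) as fh:
        raw = json.load(fh)
    return raw


def load_maxent_models(dir_: str) -> tuple[MaxEntModel, MaxEntModel]:
    """Load the donor5 and acceptor3 models from a model-table directory."""
    override = _read_consensus(dir_)
    bgd = (override or {}).get("background", DEFAULT_BACKGROUND)
    donor_cons = tuple((override or {}).get("donor_consensus", DONOR_CONSENSUS))
    acc_cons = tuple((override or {}).get("acceptor_consensus", ACCEPTOR_CONSENSUS))

    donor = MaxEntModel(
        kind="donor5",
        tables=(_read_table(os.path.join(dir_, "me2x5")),),
        background=bgd,
        consensus=donor_cons,  # type: ignore[arg-type]
    )
    acc_tables = tuple(
        _read_table(os.path.join(dir_, f"me2x3acc{i}")) for i in range(1, 10)
    )
    acceptor = MaxEntModel(
        kind="acceptor3",
        tables=acc_tables,
        background=bgd,
        consensus=acc_cons,  # type: ignore[arg-type]
    )
    return donor, acceptor


def _check_seq(seq: str, length: int) -> str:
    seq = normalize(seq)
    if len(seq) != length:
        raise ScoringError(f"expected a {length}-mer, got length {len(seq)}")
    if not set(seq) <= set("ACGT"):
        raise ScoringError(f"sequence contains non-ACGT characters: {seq}")
    return seq


def score_5ss(seq: str, model: MaxEntModel) -> float:
    """Score a donor 9-mer (3 exonic + 6 intronic bases) in bits."""
    if model.kind != "donor5":
        raise ScoringError("score_5ss requires a donor5 model")
    seq = _check_seq(seq, 9)
    cons1, cons2 = model.consensus
    bgd = model.background
    consensus = (cons1[seq[3]] / bgd[seq[3]]) * (cons2[seq[4]] / bgd[seq[4]])
    rest = seq[:3] + seq[5:]
    return math.log2(consensus * model.tables[0][_seq_index(rest)])


def score_3ss(seq: str, model: MaxEntModel) -> float:
    """Score an acceptor 23-mer (20 intronic + 3 exonic bases) in bits."""
    if model.kind != "acceptor3":
        raise ScoringError("score_3ss requires an acceptor3 model")
    seq = _check_seq(seq, 23)
    cons1, cons2 = model.consensus
    bgd = model.background
    consensus = (cons1[seq[18]] / bgd[seq[18]]) * (cons2[seq[19]] / bgd[seq[19]])
    rest = seq[:18] + seq[20:]
    log_me = 0.0
    for i, (lo, hi) in enumerate(_ACCEPTOR_WINDOWS):
        term = math.log2(model.tables[i][_seq_index(rest[lo:hi])])
        log_me += term if i < 5 else -term
    return math.log2(consensus) + log_me


def gc_fraction(seq: str) -> float:
    """GC proportion of a sequence, with N excluded from the denominator."""
    seq = normalize(seq)
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return (counts["G"] + counts["C"]) / total


def at_fraction(seq: str) -> float:
    return 1.0 - gc_fraction(seq)


def percentile_rank(x: float, population: Sequence[float] | np.ndarray) -> float:
    """Mid-rank percentile of ``x`` in ``population``: ties count half."""
    pop = np.asarray(population, dtype=float)
    pop = pop[~np.isnan(pop)]
    if pop.size == 0:
        raise ValueError("population is empty")
    # clamp: percentileofscore can stray past 100 by a floating-point ulp
    return float(min(100.0, max(0.0, stats.percentileofscore(pop, x, kind="mean"))))


BranchPointTable = Mapping[tuple[str, int, int, str], int]


def load_branchpoint_table(path: str) -> dict[tuple[str, int, int, str], int]:
    """Read a branch-point TSV (chrom, start, end, strand, bp_pos; 0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "strand", "bp_pos"}
    if not required <= set(df.columns):
        raise ValueError(f"branch-point table needs columns {sorted(required)}")
    return {
        (r.chrom, int(r.start), int(r.end), r.strand): int(r.bp_pos)
        for r in df.itertuples()
    }


def branchpoint_distance(intron: IntronRecord, bp_table: BranchPointTable) -> int | None:
    """Distance (nt) from the branch-point adenosine to the 3'ss terminal dinucleotide.

    Measured in transcript orientation to the first base of the intron's
    3'-terminal dinucleotide; None when the intron is absent from the table.
    """
    key = (intron.chrom, intron.start, intron.end, intron.strand)
    bp = bp_table.get(key)
    if bp is None:
        return None
    if not (intron.start <= bp < intron.end):
        raise ValueError(
            f"branch point {bp} outside intron [{intron.start}, {intron.end})"
        )
    if intron.strand == "+":
        dist = (intron.end - 2) - bp
    else:
        dist = bp - (intron.start + 1)
    if dist < 0:
        raise ValueError(
            f"branch point {bp} downstream of the 3'ss dinucleotide "
            f"({intron.transcript_id} intron {intron.ordinal})"
        )
    return dist


def ag_exclusion_zone(intron_seq: str, bp_offset: int) -> int | None:
    """Distance from the branch point to the nearest downstream AG (our definition).

    ``intron_seq`` is the transcript-orientation intron sequence and
    ``bp_offset`` the 0-based branch-point position within it.  Returns the
    number of nucleotides between the branch point and the next AG
    dinucleotide start, or None if no AG follows.
    """
    seq = normalize(intron_seq)
    pos = seq.find("AG", bp_offset + 1)
    return None if pos == -1 else pos - bp_offset - 1


@dataclass(frozen=True)
class IntronFeatures:
    """Features of one intron and its percentile ranks in a reference population."""

    intron: IntronRecord
    length_nt: int
    gc: float
    score5: float | None
    score3: float | None
    bp_dist: int | None
    percentiles: dict[str, float] = field(default_factory=dict)


def _intron_sequence(intron: IntronRecord, genome: Fasta | Mapping[str, str]) -> str:
    if isinstance(genome, Fasta):
        seq = str(genome[intron.chrom][intron.start : intron.end])
    else:
        seq = genome[intron.chrom][intron.start : intron.end]
    seq = normalize(seq)
    return revcomp(seq) if intron.strand == "-" else seq


def compute_intron_features(
    introns: Iterable[IntronRecord],
    genome: Fasta | Mapping[str, str],
    models: tuple[MaxEntModel, MaxEntModel] | None = None,
    bp_table: BranchPointTable | None = None,
) -> list[IntronFeatures]:
    """Length, GC, MaxEnt scores and branch-point distance for each intron.

    Introns whose scoring windows contain N get score None (they stay in the
    length/GC population but are excluded from score populations).
    """
    out: list[IntronFeatures] = []
    for intron in introns:
        seq = _intron_sequence(intron, genome)
        score5 = score3 = None
        if models is not None:
            donor, acceptor = models
            sites = splice_site_sequences(intron, genome)
            try:
                score5 = score_5ss(sites.donor9, donor)
            except ScoringError:
                score5 = None
            try:
                score3 = score_3ss(sites.acceptor23, acceptor)
            except ScoringError:
                score3 = None
        bp_dist = branchpoint_distance(intron, bp_table) if bp_table else None
        out.append(
            IntronFeatures(
                intron=intron,
                length_nt=intron.length,
                gc=gc_fraction(seq),
                score5=score5,
                score3=score3,
                bp_dist=bp_dist,
            )
        )
    return out


_FEATURE_KEYS = ("length_nt", "gc", "score5", "score3", "bp_dist")


def feature_profile(
    gene_transcript: TranscriptModel,
    genome: Fasta | Mapping[str, str],
    models: tuple[MaxEntModel, MaxEntModel] | None,
    population: Sequence[IntronFeatures],
    bp_table: BranchPointTable | None = None,
) -> tuple[list[IntronFeatures], pd.DataFrame]:
    """Profile every intron of a gene against the genome-wide population.

    Returns (per-intron features with percentile ranks, within-gene table of
    all donor and acceptor scores).
    """
    gene_introns = derive_introns(gene_transcript)
    gene_feats = compute_intron_features(gene_introns, genome, models, bp_table)

    pop_arrays: dict[str, np.ndarray] = {}
    for key in _FEATURE_KEYS:
        vals = [getattr(f, key) for f in population]
        pop_arrays[key] = np.array(
            [np.nan if v is None else float(v) for v in vals], dtype=float
        )

    ranked: list[IntronFeatures] = []
    for f in gene_feats:
        pct: dict[str, float] = {}
        for key in _FEATURE_KEYS:
            val = getattr(f, key)
            pop = pop_arrays[key]
            pop = pop[~np.isnan(pop)]
            if val is None or pop.size == 0:
                continue
            pct[key] = percentile_rank(float(val), pop)
        ranked.append(
            IntronFeatures(
                intron=f.intron,
                length_nt=f.length_nt,
                gc=f.gc,
                score5=f.score5,
                score3=f.score3,
                bp_dist=f.bp_dist,
                percentiles=pct,
            )
        )

    within_gene = pd.DataFrame(
        {
            "ordinal": [f.intron.ordinal for f in gene_feats],
            "length_nt": [f.length_nt for f in gene_feats],
            "gc": [f.gc for f in gene_feats],
            "score5": [f.score5 for f in gene_feats],
            "score3": [f.score3 for f in gene_feats],
            "bp_dist": [f.bp_dist for f in gene_feats],
        }
    )
    return ranked, within_gene


def features_table(features: Sequence[IntronFeatures]) -> pd.DataFrame:
    """TSV-ready table: one row per intron with features and percentiles."""
    rows = []
    for f in features:
        row = {
            "transcript_id": f.intron.transcript_id,
            "ordinal": f.intron.ordinal,
            "chrom": f.intron.chrom,
            "start": f.intron.start,
            "end": f.intron.end,
            "strand": f.intron.strand,
            "length_nt": f.length_nt,
            "gc": f.gc,
            "score5": f.score5,
            "score3": f.score3,
            "bp_dist": f.bp_dist,
        }
        for key, val in f.percentiles.items():
            row[f"pct_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
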